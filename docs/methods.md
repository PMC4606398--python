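# Methods

## Model

The package implements a two-part decision-analytic model of long-term
outcomes in acute coronary syndrome (ACS) patients after percutaneous
coronary intervention (PCI), comparing six months of adjunctive Chinese
herbal medicines (CHM) plus conventional treatment against conventional
treatment alone.

**Year 1 — decision tree.** The first model year is a five-branch chance
node taken directly from trial-observed annual probabilities: nonfatal MI,
nonfatal stroke, nonfatal unstable angina (UA), all-cause death, or
event-free. Branches are mutually exclusive single outcomes (no within-year
compounding); the event-free fraction is the residual. Fatal events enter
the Markov model as dead; nonfatal events enter the corresponding new-event
state.

**Years 2–10 — Markov cohort model.** Eight states: event-free, new MI,
post-MI, new stroke, post-stroke, new UA, post-UA, dead. Annual cycles to a
10-year horizon (cycle 1 is the decision-tree year, so the Markov part
contributes nine transitions). Tenure dependence is encoded structurally
rather than through time-varying matrices: each nonfatal event is followed
by exactly one cycle in a `NEW_*` tunnel state carrying the first-year
risks, after which survivors move to the chronic `POST_*` state carrying
the (lower) later-year risks. Transition matrices are therefore
time-homogeneous in the base case.

Structural choices where the source description left room:

- **Recurrence** re-enters the tunnel state of the new event (tenure
  resets); the most recent event defines the state, consistent with a
  memoryless chain. A stroke from any MI/UA state enters new-stroke; an MI
  from any stroke/UA state enters new-MI.
- **UA entry** is only possible from the event-free state; post-MI and
  post-stroke (and, with no recurrence row available, post-UA) patients
  cannot enter the UA states.
- **Competing risks within a row** are additive; the residual stays in (or
  moves on to) the source's destination state. A row whose stated outgoing
  probabilities exceed 1 is an infeasibility error, never renormalized.
- **Post-event mortality** is treated as an all-cause total; the event-free
  background death hazard is *not* added on top. A switch
  (`settings.add_background_mortality`) adds it on the hazard scale for
  exploration.
- **Age-related risk multiplier.** The parameter table lists an
  odds-ratio-like decline of MACE risk per decade (0.5, range 0.33–0.87)
  without stating where it enters the transition structure, and the
  published base-case results are reproduced without it. It is stored,
  exposed as an optional hazard-scale multiplier `OR**(cycle/10)` on all
  event and death probabilities (`settings.apply_age_or`), and disabled by
  default.

Both arms share all Markov-part probabilities; the only between-arm
differences are the year-1 event probabilities and the event-free utility,
so the arms differ solely through their state distribution after year 1.

## Outcomes

Survival at cycle *t* is one minus dead-state occupancy (undiscounted; the
published terminal survival figures are consistent with raw occupancy).

QALYs weight each state-year by an annual utility: the arm's event-free
EQ-5D utility for the event-free state; that utility minus the event's
disutility (MI 0.127, stroke 0.139, UA 0.117) for event-affected states;
zero for death. By default the disutility is subtracted for every year
spent in a new- or post-event state (`disutility_mode="persistent"`); a
`one-off` mode restricts the subtraction to the event year.

**Half-cycle correction and discounting.** Per-cycle rewards are computed
on end-of-cycle occupancy. Under the default `trapezoid` convention the
first cycle contributes half its end-of-cycle reward (events fall mid-cycle
on average) and each later cycle the mean of adjacent end-of-cycle rewards;
`entry-half` and `none` variants are available. Cycle terms are discounted
by `(1+r)^-t` with `t` the 1-based model year and `r = 0.035` per year by
default. The source reports discounted totals without printing a rate or an
exact half-cycle formula, so these two conventions were calibrated jointly:
over the candidate rates {0, 0.03, 0.035, 0.05} and the three half-cycle
variants, only trapezoid at 3.5%/year with discounting from cycle 1
reproduces the published 10-year totals (5.519/5.408) within ±0.02; the
published year-1 figures (0.405/0.396) equal the *undiscounted* first
term 0.5 × reward(end-of-year-1) under either trapezoid or entry-half, so
the year-1 QALY quantity is reported undiscounted. The resolved convention
is recorded in every run manifest.

Per-1000 event counts: event-free gained and deaths avoided compare
terminal occupancies between arms; prevented nonfatal events compare
cumulative incidence (tunnel-state occupancy summed over cycles — exact,
since tunnel occupancy at cycle *t* is the incidence during year *t*).
Differences are scaled by the cohort size (1000) and rounded half away from
zero to whole patients. Note the published report of "20 deaths avoided" is
internally inconsistent with its own survival figures: a 0.20-percentage-
point survival gain on 1000 patients is 2 patients, and deaths avoided at
the horizon is identically that terminal difference; the model reports 2.

## One-way sensitivity analysis

Every parameter with a printed range (36 in total) is set in turn to its
low and high endpoint, all else at base, and both arms are re-run. Scoping:
arm-specific year-1 probabilities vary their own arm only; long-term
probabilities, disutilities and the age multiplier are shared and affect
both arms; the two event-free utilities are varied as one *linked* level —
either range sets both arms' utility to the same varied value — so utility
variation probes the utility level, not the between-arm gap. (Varying each
arm's utility independently over the printed ranges, which are min–max
spans of individual EQ-5D scores, would swing QALYs by several units and
trivially break any dominance statement.) Records are ranked by the spread
in CHM-arm total QALYs by default (`incremental` available), ties broken by
name. `dominance_check` is true iff the incremental QALY is strictly
positive at every endpoint of every variation; it holds for the base-case
parameter set.

The published sensitivity range for event-free mortality (CHM-arm QALYs
5.505–5.532 over mortality 0.014–0.033) is not reproducible by this — or,
as far as we can tell, any — annual-cycle cohort model: a ±0.0095/year
mortality change sustained for nine years moves discounted life-years by
roughly 0.2–0.4, an order of magnitude more than the printed spread. The
faithful computation gives 5.423 (at 0.033) to 5.785 (at 0.014), and the
corresponding acceptance checks are expected to disagree with the printed
endpoints. For the same reason the published top-5 tornado ranking is not
asserted; the suite checks instead that event-free mortality is the widest
probability parameter.

## Parameters, validation, generators

All inputs ship as a packaged YAML fixture (`acsmarkov/data/base_case.yaml`,
schema in `schema.json`): per-arm year-1 probabilities, long-term
transition probabilities, utilities/disutilities, each with its printed
sensitivity range, plus run settings. Validation enforces probabilities in
[0, 1], per-row outgoing sums ≤ 1, range ordering, and non-negative
event-state utilities at base values; a base value outside its own printed
range (one table row has this) is preserved and flagged with a warning, not
rejected — fidelity to the source over internal consistency.

Because the study's inputs are point probabilities with ranges rather than
patient-level data, the generator layer samples parameter space, not
patients: `random_parameter_set(seed)` draws every ranged value uniformly
within its range; `perturb(ps, scale, seed)` moves each value a fraction
`scale` of the way to a seeded-random range endpoint; and a scenario
library provides deterministic degenerate cases with closed-form behaviour
(geometric two-state survival, zero mortality, immediate absorption,
equal/reversed arms). Passing tests on these inputs demonstrate the
arithmetic of the cohort model, not the clinical validity of the underlying
probabilities — the generators inherit every structural assumption above
and emulate no sampling noise, censoring, or patient heterogeneity.

## Numerical notes and limitations

- All computations are closed-form linear algebra on an 8×8 matrix over 10
  cycles; a base-case run takes ~2 ms and the full tornado under 0.1 s.
  Conservation holds to 1e-10 per trace row and the geometric closed form
  to 1e-12.
- Rounding of per-1000 counts is half-away-from-zero (whole patients).
- Rate↔probability conversion assumes a constant hazard within the year
  (`p = 1 − exp(−rate·t)`), implemented with `expm1`/`log1p` for small
  values.
- No costs, ICERs, probabilistic sensitivity analysis, or microsimulation:
  the model is a cohort-fraction calculation, and all uncertainty handling
  is one-way over printed ranges.
- The horizon is fixed at annual cycles; `cycle_length_years` other than 1
  is rejected rather than silently rescaled.
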