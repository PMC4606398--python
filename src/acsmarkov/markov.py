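"""Long-term Markov engine: transition matrices and cohort propagation.

Tenure dependence ("1st year" versus "after 1st year" risks) is encoded
structurally: each nonfatal event sends the patient into a one-cycle tunnel
state (``NEW_*``) carrying the first-year risks, after which survivors move
to the chronic ``POST_*`` state carrying the later-year risks. Recurrent
events re-enter the tunnel state of the new event (the model has no memory:
the most recent event defines the state). Transitions into the unstable
angina states are only possible from the event-free state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decision_tree import YearOneOutcome
from .parameters import (
    InfeasibleModelError,
    LongTermProbs,
    ModelSettings,
    probability_to_rate,
    rate_to_probability,
)
from .states import N_STATES, HealthState

_ROW_TOL = 1e-12

_S = HealthState


def _scale_probability(p: float, multiplier: float) -> float:
    """Scale a probability on the hazard scale: p -> 1 - (1-p)^multiplier."""
    if multiplier == 1.0 or p == 0.0:
        return p
    return rate_to_probability(probability_to_rate(p) * multiplier)


def build_transition_matrix(
    long_term: LongTermProbs,
    *,
    cycle: int = 1,
    apply_age_or: bool = False,
    add_background_mortality: bool = False,
) -> np.ndarray:
    """One-cycle transition matrix over the 8 states.

    Rows are from-states, columns to-states. ``cycle`` is the (1-based)
    model year the transition starts from; it only matters when the
    age-related risk multiplier is enabled, in which case every event and
    death probability is scaled on the hazard scale by ``OR**(cycle/10)``.

    ``add_background_mortality`` optionally adds the event-free death
    hazard on top of the post-event death rows (off by default: the
    post-event death probabilities are treated as all-cause totals).
    """
    ef = long_term.event_free
    mult = 1.0
    if apply_age_or:
        mult = long_term.age_mace_or_per_10y.base ** (cycle / 10.0)

    def p(ranged) -> float:
        return _scale_probability(ranged.base, mult)

    def death(ranged) -> float:
        q = p(ranged)
        if add_background_mortality:
            bg_rate = probability_to_rate(p(ef.p_death))
            q = rate_to_probability(probability_to_rate(q) + bg_rate)
        return q

    M = np.zeros((N_STATES, N_STATES))

    def fill(row: HealthState, moves: dict[HealthState, float], residual: HealthState):
        total = sum(moves.values())
        if total > 1.0 + _ROW_TOL:
            raise InfeasibleModelError(
                f"outgoing probabilities from {row.name} sum to {total:.6g} > 1"
            )
        for dest, q in moves.items():
            M[row, dest] += q
        M[row, residual] += max(1.0 - total, 0.0)

    fill(_S.EVENT_FREE,
         {_S.NEW_MI: p(ef.p_mi), _S.NEW_STROKE: p(ef.p_stroke),
          _S.NEW_UA: p(ef.p_ua), _S.DEAD: p(ef.p_death)},
         residual=_S.EVENT_FREE)

    for new, post, probs in (
        (_S.NEW_MI, _S.POST_MI, long_term.post_mi),
        (_S.NEW_UA, _S.POST_UA, long_term.post_ua),
        (_S.NEW_STROKE, _S.POST_STROKE, long_term.post_stroke),
    ):
        # tunnel state: first-year risks; survivors without a new event
        # move on to the chronic state
        fill(new,
             {_S.DEAD: death(probs.p_death_y1),
              _S.NEW_MI: p(probs.p_mi_y1),
              _S.NEW_STROKE: p(probs.p_stroke_y1)},
             residual=post)
        # chronic state: later-year risks; residual stays put
        fill(post,
             {_S.DEAD: death(probs.p_death_later),
              _S.NEW_MI: p(probs.p_mi_later),
              _S.NEW_STROKE: p(probs.p_stroke_later)},
             residual=post)

    M[_S.DEAD, _S.DEAD] = 1.0

    assert np.allclose(M.sum(axis=1), 1.0, atol=1e-9)
    return M


@dataclass
class CohortTrace:
    """State-occupancy fractions per cycle for one arm.

    Row ``t`` (0-based index ``t-1``) holds the occupancy at the end of
    model year ``t``; row 1 is the decision-tree output. Occupancy of a
    ``NEW_*`` tunnel state in a given row is exactly the incidence of that
    event during that year, so cumulative event counts are column sums.
    """

    occupancy: np.ndarray  # (horizon, N_STATES)
    arm: str = ""

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0]

    def survival(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, _S.DEAD]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.occupancy, columns=[s.name.lower() for s in HealthState]
        )
        df.insert(0, "cycle", np.arange(1, self.horizon + 1))
        df.insert(1, "arm", self.arm)
        return df


def run_cohort(
    entry: YearOneOutcome,
    long_term: LongTermProbs,
    settings: ModelSettings,
    arm: str = "",
) -> CohortTrace:
    """Propagate the cohort from the year-1 distribution to the horizon."""
    rows = np.zeros((settings.horizon_years, N_STATES))
    rows[0] = entry.as_state_vector()
    if abs(rows[0].sum() - 1.0) > 1e-9:
        raise ValueError("entry distribution does not sum to 1")
    for t in range(1, settings.horizon_years):
        M = build_transition_matrix(
            long_term,
            cycle=t,
            apply_age_or=settings.apply_age_or,
            add_background_mortality=settings.add_background_mortality,
        )
        rows[t] = rows[t - 1] @ M
    return CohortTrace(occupancy=rows, arm=arm)
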