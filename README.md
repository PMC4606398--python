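# acsmarkov

A decision-analytic model of long-term clinical outcomes in acute coronary
syndrome (ACS) patients after percutaneous coronary intervention (PCI),
comparing six months of adjunctive Chinese herbal medicines (CHM) plus
conventional treatment against conventional treatment alone. It is aimed at
health-economics and outcomes researchers who want a transparent,
scriptable reimplementation of a classic trial-based two-part model:

1. a **1-year decision tree** over five outcomes (nonfatal MI, nonfatal
   stroke, nonfatal unstable angina, all-cause death, event-free) with
   trial-observed per-arm probabilities, feeding
2. an **8-state Markov cohort model** (event-free, new/post MI, new/post
   stroke, new/post UA, dead) with annual cycles to a 10-year horizon.
   Tunnel states carry first-year post-event risks; chronic states carry
   later-year risks; death is absorbing.

Outcomes are survival curves and discounted quality-adjusted life years:
with state occupancy $\pi_t$ and per-state annual utilities $u$ (event
states valued at the arm's event-free EQ-5D utility minus an event
disutility),

$$\mathrm{QALY} = \sum_{t=1}^{10} h_t(\pi^\top u)\,(1+r)^{-t},$$

where $h_t$ is the half-cycle correction (half reward in cycle 1, adjacent-
cycle means thereafter) and $r = 0.035$/year. A one-way sensitivity module
sweeps every parameter across its published range and produces a ranked
tornado table and a dominance check.

## Worked example

```python
from acsmarkov import base_case, run_model

results = run_model(base_case())
print(f"10-year survival: CHM {results.chm.survival_10y_pct:.2f}%, "
      f"conventional {results.conv.survival_10y_pct:.2f}%")
print(f"10-year QALYs:    CHM {results.chm.qaly_total:.3f}, "
      f"conventional {results.conv.qaly_total:.3f}")
print(f"Year-1 QALYs:     CHM {results.chm.qaly_year1:.3f}, "
      f"conventional {results.conv.qaly_year1:.3f}")
print(f"Incremental QALYs: {results.incremental['qaly_total']:.3f}")
print(f"Per 1000 patients: {results.events_per_1000}")
```

prints

```
10-year survival: CHM 77.48%, conventional 77.28%
10-year QALYs:    CHM 5.534, conventional 5.423
Year-1 QALYs:     CHM 0.405, conventional 0.397
Incremental QALYs: 0.111
Per 1000 patients: {'event_free_gained': 22, 'mi_prevented': 11, 'stroke_prevented': 10, 'ua_prevented': 16, 'deaths_avoided': 2}
```

Read: over ten years the CHM arm keeps 0.20 more percentage points of the
cohort alive and accrues 0.111 additional discounted QALYs per patient; per
1000 patients it leaves 22 more event-free and avoids 2 deaths.

The same run from the shell, plus the sensitivity sweep:

```sh
acsmarkov run --out out/            # traces, survival table, results.json
acsmarkov sensitivity --out out/ --plot   # tornado.csv (+ tornado.png)
```

Every output embeds the resolved run manifest (config source, overrides,
all parameter values), and identical manifests give byte-identical files.
Conventions are switchable: `--half-cycle {trapezoid,entry-half,none}`,
`--discount-rate`, `--disutility {persistent,one-off}`, `--age-or
{on,off}`, `--horizon`, `--cohort-size`. Custom parameter sets are YAML
files validated against the shipped schema (`acsmarkov export-config` writes
the base case as a starting point).

See `docs/methods.md` for the model's assumptions, the half-cycle/discount
calibration, the sensitivity scoping rules, and known limitations.

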