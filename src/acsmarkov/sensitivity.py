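"""One-way (univariate) sensitivity analysis and tornado output.

Each ranged parameter is set in turn to its low and high endpoint with all
other parameters at base values; the model is re-run for both arms at each
endpoint. Shared parameters (long-term transition probabilities, event
disutilities, the age multiplier) naturally affect both arms. Arm-specific
first-year probabilities are varied in their own arm only. The two
event-free utilities are treated as one linked utility parameter: varying
either sets BOTH arms' event-free utility to the varied value, so the
variation probes the utility level rather than the between-arm utility gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .outcomes import ModelResults, run_model
from .parameters import ParameterSet, iter_ranged, set_base_value

#: paths varied as a linked pair (applied to both arms simultaneously)
_LINKED_UTILITIES = ("utilities.u_event_free_chm", "utilities.u_event_free_conv")


@dataclass
class SensitivityRecord:
    """Model outputs at the two endpoints of one parameter's range."""

    parameter_name: str
    low_value: float
    high_value: float
    output_at_low: dict[str, float]
    output_at_high: dict[str, float]
    spread: float

    def endpoint_incrementals(self) -> tuple[float, float]:
        return (self.output_at_low["incremental"],
                self.output_at_high["incremental"])


def apply_parameter(ps: ParameterSet, path: str, value: float) -> ParameterSet:
    """Set one parameter (or linked pair) to ``value``, all else at base."""
    if path in _LINKED_UTILITIES:
        for p in _LINKED_UTILITIES:
            ps = set_base_value(ps, p, value)
        return ps
    return set_base_value(ps, path, value)


def _outputs(results: ModelResults) -> dict[str, float]:
    return {
        "qaly_chm": results.chm.qaly_total,
        "qaly_conv": results.conv.qaly_total,
        "incremental": results.incremental["qaly_total"],
    }


def one_way_sensitivity(
    params: ParameterSet, ranking_output: str = "absolute"
) -> list[SensitivityRecord]:
    """One record per ranged parameter, sorted by descending output spread.

    ``ranking_output`` selects the spread used for ordering: ``absolute``
    (CHM-arm total QALYs, the default) or ``incremental`` (between-arm QALY
    difference). Ties are broken by parameter name.
    """
    if ranking_output not in ("absolute", "incremental"):
        raise ValueError(f"unknown ranking output {ranking_output!r}")
    key = "qaly_chm" if ranking_output == "absolute" else "incremental"
    records = []
    for path, ranged in iter_ranged(params):
        if not ranged.has_range:
            continue
        out = {}
        for endpoint in (ranged.low, ranged.high):
            out[endpoint] = _outputs(run_model(apply_parameter(params, path, endpoint)))
        lo, hi = out[ranged.low], out[ranged.high]
        records.append(SensitivityRecord(
            parameter_name=path,
            low_value=ranged.low,
            high_value=ranged.high,
            output_at_low=lo,
            output_at_high=hi,
            spread=abs(hi[key] - lo[key]),
        ))
    records.sort(key=lambda r: (-r.spread, r.parameter_name))
    return records


def dominance_check(records: list[SensitivityRecord]) -> bool:
    """True iff the CHM arm gains QALYs at every endpoint of every variation."""
    return all(
        inc > 0 for r in records for inc in r.endpoint_incrementals()
    )


def tornado_frame(records: list[SensitivityRecord]) -> pd.DataFrame:
    """Tabular tornado: one row per parameter, ranked by spread."""
    return pd.DataFrame([
        {
            "rank": i + 1,
            "parameter": r.parameter_name,
            "low": r.low_value,
            "high": r.high_value,
            "qaly_chm_at_low": r.output_at_low["qaly_chm"],
            "qaly_chm_at_high": r.output_at_high["qaly_chm"],
            "qaly_conv_at_low": r.output_at_low["qaly_conv"],
            "qaly_conv_at_high": r.output_at_high["qaly_conv"],
            "incremental_at_low": r.output_at_low["incremental"],
            "incremental_at_high": r.output_at_high["incremental"],
            "spread": r.spread,
        }
        for i, r in enumerate(records)
    ])


def plot_tornado(records: list[SensitivityRecord], path, base_value: float,
                 output: str = "qaly_chm", top: int = 15) -> None:
    """Horizontal-bar tornado plot of the ``top`` widest parameters."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    recs = records[:top][::-1]
    names = [r.parameter_name for r in recs]
    lows = [min(r.output_at_low[output], r.output_at_high[output]) for r in recs]
    highs = [max(r.output_at_low[output], r.output_at_high[output]) for r in recs]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(recs) + 1.5))
    ax.barh(names, [h - l for l, h in zip(lows, highs)], left=lows,
            color="#4878d0", edgecolor="black", linewidth=0.4)
    ax.axvline(base_value, color="black", linestyle="--", linewidth=1)
    ax.set_xlabel(output)
    ax.set_title("One-way sensitivity (tornado)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
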