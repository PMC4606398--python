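"""Outcome accounting: survival, discounted QALYs, event counts, increments.

QALYs are accumulated from end-of-cycle state occupancies with a half-cycle
correction. Under the default ``trapezoid`` convention the first cycle
contributes half of its end-of-cycle reward (events occur mid-cycle on
average) and every later cycle contributes the mean of the adjacent
end-of-cycle rewards. Per-cycle terms are discounted by ``(1+r)^-t`` with
``t`` the 1-based model year. The year-1 QALY figure is conventionally
quoted undiscounted (it equals half the utility-weighted end-of-year-1
occupancy, a closed form independent of the Markov engine).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decision_tree import run_decision_tree
from .markov import CohortTrace, run_cohort
from .parameters import ModelSettings, ParameterSet, UtilitySet
from .states import N_STATES, STATE_EVENT, HealthState

_S = HealthState

ARMS = ("chm", "conv")


def state_utilities(
    utilities: UtilitySet, arm: str, disutility_mode: str = "persistent"
) -> np.ndarray:
    """Annual utility weight of each health state for one arm.

    Event-affected states are valued at the arm's event-free utility minus
    the event disutility; under ``one-off`` mode the subtraction applies
    only in the event year (the ``NEW_*`` tunnel states). Death is 0.
    """
    u = utilities.event_free_utility(arm).base
    d = {"mi": utilities.d_mi.base, "stroke": utilities.d_stroke.base,
         "ua": utilities.d_ua.base}
    w = np.zeros(N_STATES)
    w[_S.EVENT_FREE] = u
    for state, event in STATE_EVENT.items():
        if disutility_mode == "one-off" and state.name.startswith("POST"):
            w[state] = u
        else:
            w[state] = u - d[event]
    w[_S.DEAD] = 0.0
    if (w < 0).any():
        bad = HealthState(int(np.argmin(w))).name
        raise ValueError(f"computed utility of state {bad} is negative")
    return w


def cycle_reward(
    occupancy_row: np.ndarray,
    utilities: UtilitySet,
    arm: str,
    disutility_mode: str = "persistent",
) -> float:
    """Utility-weighted reward of one occupancy row (QALYs per year)."""
    if abs(float(occupancy_row.sum()) - 1.0) > 1e-9:
        raise ValueError("occupancy row does not sum to 1")
    return float(occupancy_row @ state_utilities(utilities, arm, disutility_mode))


def compute_survival(trace: CohortTrace) -> tuple[np.ndarray, float]:
    """Per-cycle survival curve and the terminal value as a percentage."""
    curve = trace.survival()
    return curve, float(curve[-1] * 100.0)


def _half_cycle_terms(rewards: np.ndarray, convention: str) -> np.ndarray:
    r = np.asarray(rewards, dtype=float)
    if convention == "none":
        return r
    terms = np.empty_like(r)
    terms[0] = 0.5 * r[0]
    if convention == "entry-half":
        terms[1:] = r[1:]
    elif convention == "trapezoid":
        terms[1:] = 0.5 * (r[:-1] + r[1:])
    else:
        raise ValueError(f"unknown half-cycle convention {convention!r}")
    return terms


def compute_qalys(
    trace: CohortTrace,
    utilities: UtilitySet,
    settings: ModelSettings,
    arm: str,
) -> tuple[float, float]:
    """Discounted total QALYs over the horizon and the year-1 QALY figure."""
    rewards = np.array([
        cycle_reward(row, utilities, arm, settings.disutility_mode)
        for row in trace.occupancy
    ])
    terms = _half_cycle_terms(rewards, settings.half_cycle)
    t = np.arange(1, trace.horizon + 1)
    discount = (1.0 + settings.discount_rate) ** (-t)
    qaly_total = float(terms @ discount)
    qaly_year1 = float(terms[0])  # quoted undiscounted by convention
    return qaly_total, qaly_year1


def cumulative_events(trace: CohortTrace) -> dict[str, float]:
    """Cumulative incident nonfatal events (cohort fractions).

    Tunnel-state occupancy at cycle t is exactly the incidence during
    year t, so cumulative incidence is the column sum over cycles.
    """
    occ = trace.occupancy
    return {
        "mi": float(occ[:, _S.NEW_MI].sum()),
        "stroke": float(occ[:, _S.NEW_STROKE].sum()),
        "ua": float(occ[:, _S.NEW_UA].sum()),
    }


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def events_per_cohort(
    trace_chm: CohortTrace, trace_conv: CohortTrace, cohort_size: int = 1000
) -> dict[str, int]:
    """Between-arm event differences scaled to a cohort of ``cohort_size``.

    Event-free gained and deaths avoided compare terminal occupancies;
    prevented nonfatal events compare cumulative incidence.
    """
    if trace_chm.horizon != trace_conv.horizon:
        raise ValueError("traces do not share a horizon")
    ev_chm, ev_conv = cumulative_events(trace_chm), cumulative_events(trace_conv)
    diffs = {
        "event_free_gained": trace_chm.occupancy[-1, _S.EVENT_FREE]
        - trace_conv.occupancy[-1, _S.EVENT_FREE],
        "mi_prevented": ev_conv["mi"] - ev_chm["mi"],
        "stroke_prevented": ev_conv["stroke"] - ev_chm["stroke"],
        "ua_prevented": ev_conv["ua"] - ev_chm["ua"],
        "deaths_avoided": trace_conv.occupancy[-1, _S.DEAD]
        - trace_chm.occupancy[-1, _S.DEAD],
    }
    return {k: _round_half_away(v * cohort_size) for k, v in diffs.items()}


@dataclass
class ArmResults:
    """Per-arm outputs of one model run."""

    arm: str
    trace: CohortTrace
    survival_curve: np.ndarray
    survival_10y_pct: float
    qaly_total: float
    qaly_year1: float
    cumulative_events: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "survival_curve": [float(x) for x in self.survival_curve],
            "survival_10y_pct": self.survival_10y_pct,
            "qaly_total": self.qaly_total,
            "qaly_year1": self.qaly_year1,
            "cumulative_events": self.cumulative_events,
        }


@dataclass
class ModelResults:
    """Both arms plus incremental comparisons and per-cohort event counts."""

    chm: ArmResults
    conv: ArmResults
    incremental: dict[str, float] = field(default_factory=dict)
    events_per_1000: dict[str, int] = field(default_factory=dict)

    def arm(self, name: str) -> ArmResults:
        return self.chm if name == "chm" else self.conv

    def to_dict(self) -> dict:
        return {
            "chm": self.chm.to_dict(),
            "conv": self.conv.to_dict(),
            "incremental": self.incremental,
            "events_per_1000": self.events_per_1000,
        }


def run_arm(params: ParameterSet, arm: str) -> ArmResults:
    entry = run_decision_tree(params.arm(arm))
    trace = run_cohort(entry, params.long_term, params.settings, arm=arm)
    curve, terminal = compute_survival(trace)
    qaly_total, qaly_year1 = compute_qalys(trace, params.utilities, params.settings, arm)
    return ArmResults(
        arm=arm,
        trace=trace,
        survival_curve=curve,
        survival_10y_pct=terminal,
        qaly_total=qaly_total,
        qaly_year1=qaly_year1,
        cumulative_events=cumulative_events(trace),
    )


def incremental(results_chm: ArmResults, results_conv: ArmResults) -> dict[str, float]:
    """Differences (CHM arm minus conventional arm) of the headline outputs."""
    return {
        "qaly_total": results_chm.qaly_total - results_conv.qaly_total,
        "qaly_year1": results_chm.qaly_year1 - results_conv.qaly_year1,
        "survival_10y_pct_points": results_chm.survival_10y_pct
        - results_conv.survival_10y_pct,
    }


def run_model(params: ParameterSet) -> ModelResults:
    """Run both arms and assemble all base-case outputs."""
    chm = run_arm(params, "chm")
    conv = run_arm(params, "conv")
    return ModelResults(
        chm=chm,
        conv=conv,
        incremental=incremental(chm, conv),
        events_per_1000=events_per_cohort(
            chm.trace, conv.trace, params.settings.cohort_size
        ),
    )
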