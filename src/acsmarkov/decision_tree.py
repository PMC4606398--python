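"""Year-1 decision tree: distribute the cohort over Markov entry states.

The first model year is a five-branch chance node taken directly from the
trial: nonfatal MI, nonfatal stroke, nonfatal unstable angina, all-cause
death, or event-free. Branches are mutually exclusive (no within-year
compounding); survivors of a nonfatal event enter the corresponding tunnel
state of the Markov model, deaths enter the absorbing dead state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ArmYearOneProbs, InfeasibleModelError
from .states import N_STATES, HealthState

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class YearOneOutcome:
    """End-of-year-1 cohort fractions over the five decision-tree outcomes."""

    fraction_event_free: float
    fraction_new_mi: float
    fraction_new_stroke: float
    fraction_new_ua: float
    fraction_dead: float

    def as_state_vector(self) -> np.ndarray:
        """Map the outcome onto the 8-state occupancy vector (cycle 1)."""
        v = np.zeros(N_STATES)
        v[HealthState.EVENT_FREE] = self.fraction_event_free
        v[HealthState.NEW_MI] = self.fraction_new_mi
        v[HealthState.NEW_STROKE] = self.fraction_new_stroke
        v[HealthState.NEW_UA] = self.fraction_new_ua
        v[HealthState.DEAD] = self.fraction_dead
        return v


def run_decision_tree(arm: ArmYearOneProbs) -> YearOneOutcome:
    """Evaluate the year-1 chance node for one treatment arm.

    Each event fraction equals its annual probability; the residual
    fraction is event-free. Raises :class:`InfeasibleModelError` if the
    event probabilities sum beyond 1.
    """
    p = arm.base_values()
    total = sum(p.values())
    if total > 1.0 + _SUM_TOL:
        raise InfeasibleModelError(
            f"year-1 event probabilities sum to {total:.6g} > 1"
        )
    return YearOneOutcome(
        fraction_event_free=max(1.0 - total, 0.0),
        fraction_new_mi=p["p_nonfatal_mi"],
        fraction_new_stroke=p["p_nonfatal_stroke"],
        fraction_new_ua=p["p_nonfatal_ua"],
        fraction_dead=p["p_death"],
    )
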