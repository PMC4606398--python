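"""Deterministic test scenarios and seeded parameter perturbations.

The model's inputs are point probabilities with ranges, not patient-level
data, so the generator layer samples parameter space: a library of named
closed-form/degenerate scenarios plus a seeded perturbation operator that
pushes ranged values toward their endpoints.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .parameters import ParameterSet, iter_ranged, base_case, set_base_value


def _zero_mortality() -> ParameterSet:
    ps = base_case()
    for path, _ in iter_ranged(ps):
        if "death" in path:
            ps = set_base_value(ps, path, 0.0)
    return ps


def _immediate_absorption() -> ParameterSet:
    # whole cohort dies in year 1 (and any survivor path dies next cycle);
    # zero the event branches first so death can take the whole row
    ps = base_case()
    for path, _ in iter_ranged(ps):
        leaf = path.rsplit(".", 1)[-1]
        if leaf.startswith(("p_nonfatal", "p_mi", "p_stroke", "p_ua")):
            ps = set_base_value(ps, path, 0.0)
    for path, _ in iter_ranged(ps):
        if "death" in path.rsplit(".", 1)[-1]:
            ps = set_base_value(ps, path, 1.0)
    return ps


def _two_state_geometric() -> ParameterSet:
    # only event-free mortality is non-zero: survival follows the
    # geometric closed form (1 - p)^(t-1) from an all-event-free entry
    ps = base_case()
    for path, _ in iter_ranged(ps):
        leaf = path.rsplit(".", 1)[-1]
        if leaf.startswith("p_") and path != "long_term.event_free.p_death":
            ps = set_base_value(ps, path, 0.0)
    return set_base_value(ps, "long_term.event_free.p_death", 0.027)


def _reversed_dominance() -> ParameterSet:
    # swap the arm columns (probabilities and utilities): the conventional
    # arm gets the better inputs, reversing the direction of every increment
    ps = base_case()
    data = ps.model_dump()
    data["chm_arm"], data["conv_arm"] = data["conv_arm"], data["chm_arm"]
    u = data["utilities"]
    u["u_event_free_chm"], u["u_event_free_conv"] = (
        u["u_event_free_conv"], u["u_event_free_chm"])
    return ParameterSet.model_validate(data)


def _equal_arms() -> ParameterSet:
    ps = base_case()
    data = ps.model_dump()
    data["chm_arm"] = data["conv_arm"]
    data["utilities"]["u_event_free_chm"] = data["utilities"]["u_event_free_conv"]
    return ParameterSet.model_validate(data)


_SCENARIOS: dict[str, Callable[[], ParameterSet]] = {
    "base_case": base_case,
    "zero_mortality": _zero_mortality,
    "immediate_absorption": _immediate_absorption,
    "two_state_geometric": _two_state_geometric,
    "reversed_dominance": _reversed_dominance,
    "equal_arms": _equal_arms,
}


def scenario_names() -> tuple[str, ...]:
    return tuple(sorted(_SCENARIOS))


def scenario(name: str) -> ParameterSet:
    """Return a named deterministic scenario parameter set."""
    try:
        builder = _SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(scenario_names())}"
        ) from None
    return builder()


def perturb(params: ParameterSet, scale: float, seed: int) -> ParameterSet:
    """Move every ranged value toward a randomly chosen range endpoint.

    Each ranged parameter moves a fraction ``scale`` of the distance from
    its base value to a (seeded, uniformly chosen) endpoint of its range:
    ``scale=0`` returns the input unchanged, ``scale=1`` puts every value
    exactly at an endpoint. Deterministic for a given seed.
    """
    if not 0.0 <= scale <= 1.0:
        raise ValueError(f"scale must be in [0, 1], got {scale}")
    rng = np.random.default_rng(seed)
    ps = params
    for path, ranged in iter_ranged(params):
        if not ranged.has_range:
            continue
        endpoint = ranged.low if rng.random() < 0.5 else ranged.high
        ps = set_base_value(ps, path, (1.0 - scale) * ranged.base + scale * endpoint)
    return ps
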