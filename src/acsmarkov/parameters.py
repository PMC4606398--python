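"""Model parameters: annual event probabilities, utilities, and settings.

The entire data surface of the model is a small set of annual probabilities
and utility weights, each carried as a base value with an optional
sensitivity range. Parameters live in three blocks:

* per-arm first-year event probabilities (trial-observed, decision tree),
* long-term transition probabilities shared by both arms (Markov part),
* EQ-5D-derived utilities and event disutilities.

Parameter sets serialize losslessly to YAML; a JSON schema generated from
the pydantic models is shipped alongside the packaged base-case fixture.
"""

from __future__ import annotations

import math
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterator, Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "Ranged",
    "ArmYearOneProbs",
    "EventFreeProbs",
    "PostEventProbs",
    "LongTermProbs",
    "UtilitySet",
    "ModelSettings",
    "ParameterSet",
    "ParameterWarning",
    "InfeasibleModelError",
    "base_case",
    "load_parameters",
    "write_parameters",
    "random_parameter_set",
    "iter_ranged",
    "set_base_value",
    "rate_to_probability",
    "probability_to_rate",
]

_SUM_TOL = 1e-12


class ParameterWarning(UserWarning):
    """A parameter is suspicious (e.g. base value outside its own range)."""


class InfeasibleModelError(ValueError):
    """Outgoing probabilities of a chance node or matrix row exceed 1."""


class Ranged(BaseModel):
    """A scalar parameter with an optional (low, high) sensitivity range."""

    model_config = ConfigDict(extra="forbid")

    base: float
    low: Optional[float] = None
    high: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "Ranged":
        if (self.low is None) != (self.high is None):
            raise ValueError("low and high must be given together")
        if self.low is not None and self.low > self.high:
            raise ValueError(f"low ({self.low}) exceeds high ({self.high})")
        return self

    @property
    def has_range(self) -> bool:
        return self.low is not None


def _rv(base: float, low: float | None = None, high: float | None = None) -> Ranged:
    return Ranged(base=base, low=low, high=high)


def _check_unit_interval(model: BaseModel, kind: str = "probability") -> None:
    for name, value in model:
        if not isinstance(value, Ranged):
            continue
        for part in ("base", "low", "high"):
            v = getattr(value, part)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"{name}.{part} = {v} is not a valid {kind} (must be in [0, 1])"
                )


class ArmYearOneProbs(BaseModel):
    """First-year event probabilities for one treatment arm.

    The four events (nonfatal MI, nonfatal stroke, nonfatal unstable angina,
    all-cause death) are mutually exclusive branches of the year-1 decision
    tree; the residual fraction remains event-free.
    """

    model_config = ConfigDict(extra="forbid")

    p_nonfatal_mi: Ranged
    p_nonfatal_stroke: Ranged
    p_nonfatal_ua: Ranged
    p_death: Ranged

    @model_validator(mode="after")
    def _check(self) -> "ArmYearOneProbs":
        _check_unit_interval(self)
        total = sum(v.base for _, v in self)
        if total > 1.0 + _SUM_TOL:
            raise InfeasibleModelError(
                f"year-1 event probabilities sum to {total:.6g} > 1"
            )
        return self

    def base_values(self) -> dict[str, float]:
        return {name: v.base for name, v in self}


class EventFreeProbs(BaseModel):
    """Annual risks for event-free patients in the Markov part."""

    model_config = ConfigDict(extra="forbid")

    p_mi: Ranged
    p_stroke: Ranged
    p_ua: Ranged
    p_death: Ranged

    @model_validator(mode="after")
    def _check(self) -> "EventFreeProbs":
        _check_unit_interval(self)
        total = sum(v.base for _, v in self)
        if total > 1.0 + _SUM_TOL:
            raise InfeasibleModelError(
                f"event-free outgoing probabilities sum to {total:.6g} > 1"
            )
        return self


class PostEventProbs(BaseModel):
    """Annual risks after a nonfatal event, split by tenure.

    ``*_y1`` applies in the first year after the event (the tunnel state),
    ``*_later`` from the second year onward (the chronic post-event state).
    """

    model_config = ConfigDict(extra="forbid")

    p_death_y1: Ranged
    p_death_later: Ranged
    p_mi_y1: Ranged
    p_mi_later: Ranged
    p_stroke_y1: Ranged
    p_stroke_later: Ranged

    @model_validator(mode="after")
    def _check(self) -> "PostEventProbs":
        _check_unit_interval(self)
        for suffix in ("y1", "later"):
            total = sum(
                getattr(self, f"p_{ev}_{suffix}").base
                for ev in ("death", "mi", "stroke")
            )
            if total > 1.0 + _SUM_TOL:
                raise InfeasibleModelError(
                    f"post-event '{suffix}' probabilities sum to {total:.6g} > 1"
                )
        return self


class LongTermProbs(BaseModel):
    """All transition probabilities of the long-term Markov model."""

    model_config = ConfigDict(extra="forbid")

    event_free: EventFreeProbs
    post_mi: PostEventProbs
    post_ua: PostEventProbs
    post_stroke: PostEventProbs
    #: odds-ratio-like decline of MACE risk per decade of ageing; stored for
    #: sensitivity analysis, only applied when settings.apply_age_or is set
    age_mace_or_per_10y: Ranged

    @model_validator(mode="after")
    def _check(self) -> "LongTermProbs":
        v = self.age_mace_or_per_10y
        for part in ("base", "low", "high"):
            x = getattr(v, part)
            if x is not None and x <= 0:
                raise ValueError(f"age_mace_or_per_10y.{part} must be positive")
        return self


class UtilitySet(BaseModel):
    """Annual utility weights and event disutilities.

    Utilities are on the EQ-5D scale (0 = death, 1 = full health). Event
    states are valued as the arm's event-free utility minus the event's
    disutility; death has utility 0.
    """

    model_config = ConfigDict(extra="forbid")

    u_event_free_chm: Ranged
    u_event_free_conv: Ranged
    d_mi: Ranged
    d_stroke: Ranged
    d_ua: Ranged
    d_death: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "UtilitySet":
        _check_unit_interval(self, kind="utility weight")
        if self.d_death != 0.0:
            raise ValueError("d_death must be 0 (death carries zero utility)")
        for arm in ("u_event_free_chm", "u_event_free_conv"):
            u = getattr(self, arm).base
            for d in ("d_mi", "d_stroke", "d_ua"):
                if u - getattr(self, d).base < 0:
                    raise ValueError(
                        f"{arm} - {d} is negative at base values; "
                        "event-state utility would fall below 0"
                    )
        return self

    def event_free_utility(self, arm: str) -> Ranged:
        if arm == "chm":
            return self.u_event_free_chm
        if arm == "conv":
            return self.u_event_free_conv
        raise ValueError(f"unknown arm {arm!r} (expected 'chm' or 'conv')")


class ModelSettings(BaseModel):
    """Run settings and accounting conventions.

    ``half_cycle`` selects the half-cycle correction applied to per-cycle
    rewards: ``trapezoid`` (default; half reward for the first cycle, mean
    of adjacent end-of-cycle rewards thereafter), ``entry-half`` (half
    reward for the first cycle, full end-of-cycle rewards thereafter) or
    ``none``. ``disutility_mode`` controls whether event disutilities are
    subtracted every year spent in an event or post-event state
    (``persistent``, default) or only in the event year (``one-off``).
    """

    model_config = ConfigDict(extra="forbid")

    horizon_years: int = Field(default=10, ge=1)
    cycle_length_years: float = 1.0
    discount_rate: float = Field(default=0.035, ge=0.0)
    half_cycle: Literal["trapezoid", "entry-half", "none"] = "trapezoid"
    disutility_mode: Literal["persistent", "one-off"] = "persistent"
    apply_age_or: bool = False
    #: add event-free background mortality on top of post-event death rows
    #: (off by default: post-event death probabilities are all-cause totals)
    add_background_mortality: bool = False
    cohort_size: int = Field(default=1000, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "ModelSettings":
        if self.cycle_length_years != 1.0:
            raise ValueError("the model is defined on annual cycles only")
        return self


class ParameterSet(BaseModel):
    """The full model input: both arms, long-term risks, utilities, settings."""

    model_config = ConfigDict(extra="forbid")

    chm_arm: ArmYearOneProbs
    conv_arm: ArmYearOneProbs
    long_term: LongTermProbs
    utilities: UtilitySet
    settings: ModelSettings = Field(default_factory=ModelSettings)

    def arm(self, name: str) -> ArmYearOneProbs:
        if name == "chm":
            return self.chm_arm
        if name == "conv":
            return self.conv_arm
        raise ValueError(f"unknown arm {name!r} (expected 'chm' or 'conv')")

    def range_warnings(self) -> list[str]:
        """Messages for parameters whose base value lies outside its range.

        The printed source tables contain one such row; the value is kept
        exactly as printed and flagged rather than rejected.
        """
        msgs = []
        for name, ranged in iter_ranged(self):
            if ranged.has_range and not ranged.low <= ranged.base <= ranged.high:
                msgs.append(
                    f"{name}: base {ranged.base} outside its sensitivity "
                    f"range [{ranged.low}, {ranged.high}]"
                )
        return msgs


# --- parameter traversal ---------------------------------------------------

#: dotted paths of every Ranged parameter, in a fixed deterministic order
_RANGED_PATHS: tuple[str, ...] = tuple(
    [f"{arm}.{p}" for arm in ("chm_arm", "conv_arm")
     for p in ("p_nonfatal_mi", "p_nonfatal_stroke", "p_nonfatal_ua", "p_death")]
    + [f"long_term.event_free.{p}" for p in ("p_mi", "p_stroke", "p_ua", "p_death")]
    + [f"long_term.{s}.{p}" for s in ("post_mi", "post_ua", "post_stroke")
       for p in ("p_death_y1", "p_death_later", "p_mi_y1", "p_mi_later",
                 "p_stroke_y1", "p_stroke_later")]
    + ["long_term.age_mace_or_per_10y"]
    + [f"utilities.{p}" for p in ("u_event_free_chm", "u_event_free_conv",
                                  "d_mi", "d_stroke", "d_ua")]
)


def _resolve(ps: ParameterSet, path: str) -> Ranged:
    obj = ps
    for part in path.split("."):
        obj = getattr(obj, part)
    return obj


def iter_ranged(ps: ParameterSet) -> Iterator[tuple[str, Ranged]]:
    """Yield ``(dotted_name, Ranged)`` for every scalar model parameter."""
    for path in _RANGED_PATHS:
        yield path, _resolve(ps, path)


def set_base_value(ps: ParameterSet, path: str, value: float) -> ParameterSet:
    """Return a new, revalidated ParameterSet with one base value replaced."""
    data = ps.model_dump()
    node = data
    *parents, leaf = path.split(".")
    for part in parents:
        node = node[part]
    node[leaf]["base"] = float(value)
    return ParameterSet.model_validate(data)


# --- the printed base case -------------------------------------------------

def base_case() -> ParameterSet:
    """The published base-case parameter set (values as printed)."""
    return ParameterSet(
        chm_arm=ArmYearOneProbs(
            p_nonfatal_mi=_rv(0.005, 0.0, 0.0119),
            p_nonfatal_stroke=_rv(0.0074, 0.0, 0.0158),
            p_nonfatal_ua=_rv(0.0149, 0.0031, 0.0267),
            p_death=_rv(0.0050, 0.0, 0.0119),
        ),
        conv_arm=ArmYearOneProbs(
            p_nonfatal_mi=_rv(0.0175, 0.0047, 0.0303),
            p_nonfatal_stroke=_rv(0.0150, 0.0031, 0.0269),
            p_nonfatal_ua=_rv(0.0399, 0.0207, 0.0591),
            p_death=_rv(0.0075, 0.0, 0.0159),
        ),
        long_term=LongTermProbs(
            event_free=EventFreeProbs(
                p_mi=_rv(0.018, 0.010, 0.020),
                p_stroke=_rv(0.007, 0.001, 0.009),
                p_ua=_rv(0.03, 0.02, 0.05),
                p_death=_rv(0.027, 0.014, 0.033),
            ),
            post_mi=PostEventProbs(
                p_death_y1=_rv(0.039, 0.008, 0.076),
                p_death_later=_rv(0.021, 0.003, 0.027),
                p_mi_y1=_rv(0.024, 0.002, 0.060),
                p_mi_later=_rv(0.018, 0.001, 0.008),  # printed base lies outside range
                p_stroke_y1=_rv(0.010, 0.0024, 0.024),
                p_stroke_later=_rv(0.007, 0.0008, 0.022),
            ),
            post_ua=PostEventProbs(
                p_death_y1=_rv(0.034, 0.012, 0.050),
                p_death_later=_rv(0.020, 0.016, 0.028),
                p_mi_y1=_rv(0.036, 0.01, 0.05),
                p_mi_later=_rv(0.011, 0.010, 0.063),
                p_stroke_y1=_rv(0.018, 0.014, 0.023),
                p_stroke_later=_rv(0.008, 0.006, 0.01),
            ),
            post_stroke=PostEventProbs(
                p_death_y1=_rv(0.115, 0.066, 0.189),
                p_death_later=_rv(0.035, 0.016, 0.061),
                p_mi_y1=_rv(0.003, 0.002, 0.006),
                p_mi_later=_rv(0.004, 0.002, 0.006),
                p_stroke_y1=_rv(0.128, 0.064, 0.189),
                p_stroke_later=_rv(0.040, 0.030, 0.080),
            ),
            age_mace_or_per_10y=_rv(0.5, 0.33, 0.87),
        ),
        utilities=UtilitySet(
            u_event_free_chm=_rv(0.818, 0.418, 0.848),
            u_event_free_conv=_rv(0.809, 0.252, 0.848),
            d_mi=_rv(0.127, 0.108, 0.147),
            d_stroke=_rv(0.139, 0.118, 0.160),
            d_ua=_rv(0.117, 0.100, 0.135),
        ),
    )


# --- IO --------------------------------------------------------------------

def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a parameter set from a YAML config file.

    Raises pydantic ``ValidationError`` naming the offending field for
    schema or range violations; emits :class:`ParameterWarning` for base
    values outside their own sensitivity range.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    ps = ParameterSet.model_validate(data)
    for msg in ps.range_warnings():
        warnings.warn(msg, ParameterWarning, stacklevel=2)
    return ps


def write_parameters(ps: ParameterSet, path: str | Path) -> None:
    """Write a parameter set to YAML (lossless round-trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(ps.model_dump(), fh, sort_keys=False)


def packaged_fixture_path() -> Path:
    """Path of the shipped base-case config file."""
    return Path(resources.files("acsmarkov").joinpath("data", "base_case.yaml"))


# --- random generation -----------------------------------------------------

def random_parameter_set(seed: int) -> ParameterSet:
    """A structurally valid parameter set drawn uniformly within ranges.

    Every parameter with a sensitivity range is sampled uniformly on
    [low, high]; parameters without a range keep their base value.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    ps = base_case()
    for path, ranged in iter_ranged(ps):
        if ranged.has_range:
            ps = set_base_value(ps, path, float(rng.uniform(ranged.low, ranged.high)))
    return ps


# --- rate/probability conversion -------------------------------------------

def rate_to_probability(rate: float, t: float = 1.0) -> float:
    """Probability of at least one event in time ``t`` under a constant hazard.

    ``p = 1 - exp(-rate * t)``, the standard conversion used to turn
    annualized event rates from the literature into per-cycle transition
    probabilities.
    """
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    if t <= 0:
        raise ValueError(f"time interval must be positive, got {t}")
    return -math.expm1(-rate * t)


def probability_to_rate(p: float, t: float = 1.0) -> float:
    """Inverse of :func:`rate_to_probability`: ``rate = -ln(1 - p) / t``."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    if t <= 0:
        raise ValueError(f"time interval must be positive, got {t}")
    return -math.log1p(-p) / t
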