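"""Anxiety states, phase plan, correction variable, and stimulus mappings.

The controller's job is to keep the user's normalized EDA inside a desired
band by adjusting five spider parameters.  The driving quantity is the
*correction* variable

    c = representative_value_of_desired_state - normalized_EDA

so c < 0 means the user is calmer than desired and every mapping must
strengthen the stimulus; all five mappings are monotonically non-increasing
in c.  States and their bands (normalized EDA):

    REST  [0.92, 1.0]   representative 0.92   (no stimuli)
    LOW   [0.70, 0.8]   representative 0.70   (mildly anxious)
    HIGH  [0.40, 0.5]   representative 0.40   (highly anxious)

The five mappings, with c the correction:

    SGF (generation frequency, "fps" units, rate-like: larger = more spawns):
        HIGH: 1040 - 1200 (c + 0.6);  LOW: 840 - 1200 (c + 0.6); floor 0
    SJF (jumping force, N): 0.035 - 0.14 c, floor 0.
        The printed closed form of this mapping is typographically garbled in
        the source material; this linear reconstruction exactly matches both
        published anchor values (0.035 N at c=0, 0.049 N at c=-0.1) and is
        monotone in the required direction.  The coefficients are
        configurable should a better reading emerge.
    SPU (probability of detouring toward the user): (1 - (c + 0.6)/1.4)^2,
        clamped to [0, 1].
    SS  (size scale vs. designer size): 0.3 + 0.9 * 0.2^c
    SV  (velocity, meters per frame-step): 0.006 - 0.003 (c + 0.6)/1.4,
        floored at a small positive value.

At on-target corrections (c in [-0.1, 0]) these yield SGF 120-240 (LOW) /
320-440 (HIGH), SJF 0.035-0.049 N, SPU 0.3265-0.4132, SS 1.20-1.357, and
SV 0.00471-0.00492.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

__all__ = [
    "StateLabel",
    "AnxietyState",
    "Correction",
    "StimulusParams",
    "PhasePlan",
    "ControllerConfig",
    "DEFAULT_CONFIG",
    "REST",
    "LOW",
    "HIGH",
    "STATES",
    "correction",
    "sgf",
    "sjf",
    "spu",
    "ss",
    "sv",
    "map_parameters",
    "static_schedule",
    "phase_at",
]


class StateLabel(str, enum.Enum):
    REST = "REST"
    LOW = "LOW"
    HIGH = "HIGH"

    def __str__(self) -> str:  # nicer in logs
        return self.value


@dataclass(frozen=True)
class AnxietyState:
    """A desired band of normalized EDA; the representative value is the
    band's lower edge and is what the correction variable is computed from."""

    label: StateLabel
    band_low: float
    band_high: float

    def __post_init__(self) -> None:
        if not 0.0 < self.band_low < self.band_high <= 1.0:
            raise ValueError("require 0 < band_low < band_high <= 1")

    @property
    def representative(self) -> float:
        return self.band_low

    @property
    def band(self) -> Tuple[float, float]:
        return (self.band_low, self.band_high)


REST = AnxietyState(StateLabel.REST, 0.92, 1.0)
LOW = AnxietyState(StateLabel.LOW, 0.70, 0.8)
HIGH = AnxietyState(StateLabel.HIGH, 0.40, 0.5)

STATES: Dict[StateLabel, AnxietyState] = {s.label: s for s in (REST, LOW, HIGH)}


@dataclass(frozen=True)
class Correction:
    """Desired minus observed normalized EDA.

    Negative: the user is less anxious than desired, the stimulus must
    strengthen.  Zero or positive: the stimulus must weaken.
    """

    value: float


@dataclass(frozen=True)
class StimulusParams:
    """The five-parameter bundle the controller emits.

    sgf: generation frequency ("fps" units, rate-like); sjf: jumping force
    in Newtons; spu: detour probability in [0, 1]; ss: size scale relative
    to the designer size; sv: velocity in meters per frame-step.  A REST
    bundle is all-zero (no stimuli); for active-state bundles ss and sv are
    strictly positive.
    """

    sgf: float
    sjf: float
    spu: float
    ss: float
    sv: float

    def __post_init__(self) -> None:
        if self.sgf < 0 or self.sjf < 0 or self.ss < 0 or self.sv < 0:
            raise ValueError("stimulus parameters must be non-negative")
        if not 0.0 <= self.spu <= 1.0:
            raise ValueError("spu must be a probability")

    def astuple(self) -> Tuple[float, float, float, float, float]:
        return (self.sgf, self.sjf, self.spu, self.ss, self.sv)


ZERO_PARAMS = StimulusParams(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ControllerConfig:
    """Tunable coefficients of the five mappings and the static schedule.

    Defaults reproduce the published anchor values; every clamp floor exists
    only to keep the closed forms physical outside their on-target range
    (SGF goes negative for c >= 0.1 in LOW, SPU exceeds 1 for c < -0.6).
    """

    sgf_intercepts: Tuple[float, float] = (840.0, 1040.0)  # (LOW, HIGH)
    sgf_slope: float = 1200.0
    sgf_offset: float = 0.6
    sjf_intercept: float = 0.035
    sjf_slope: float = -0.14
    spu_offset: float = 0.6
    spu_scale: float = 1.4
    ss_base: float = 0.3
    ss_gain: float = 0.9
    ss_decay: float = 0.2
    sv_base: float = 0.006
    sv_gain: float = 0.003
    sv_offset: float = 0.6
    sv_scale: float = 1.4
    sv_floor: float = 1e-4
    # feedback-independent corrections realizing the pre-recorded schedule
    static_correction_low: float = 0.0
    static_correction_high: float = -0.1


DEFAULT_CONFIG = ControllerConfig()


def correction(state: AnxietyState, normalized: float) -> Correction:
    """Correction variable: state representative minus normalized EDA."""
    if normalized <= 0:
        raise ValueError("normalized EDA must be positive")
    return Correction(state.representative - normalized)


def _c(corr) -> float:
    return corr.value if isinstance(corr, Correction) else float(corr)


def sgf(state_label: StateLabel, corr, config: ControllerConfig = DEFAULT_CONFIG) -> float:
    """Stimulus Generation Frequency; 0 in REST and when the line clamps."""
    label = StateLabel(state_label)
    if label is StateLabel.REST:
        return 0.0
    intercept = config.sgf_intercepts[0 if label is StateLabel.LOW else 1]
    return max(0.0, intercept - config.sgf_slope * (_c(corr) + config.sgf_offset))


def sjf(corr, config: ControllerConfig = DEFAULT_CONFIG) -> float:
    """Stimulus Jumping Force in Newtons (linear anchor reconstruction)."""
    return max(0.0, config.sjf_intercept + config.sjf_slope * _c(corr))


def spu(corr, config: ControllerConfig = DEFAULT_CONFIG) -> float:
    """Probability that a spider detours toward the user, clamped to [0, 1]."""
    p = (1.0 - (_c(corr) + config.spu_offset) / config.spu_scale) ** 2
    return min(1.0, max(0.0, p))


def ss(corr, config: ControllerConfig = DEFAULT_CONFIG) -> float:
    """Spider size scale; exponential in -c, always above the base size."""
    return config.ss_base + config.ss_gain * config.ss_decay ** _c(corr)


def sv(corr, config: ControllerConfig = DEFAULT_CONFIG) -> float:
    """Spider velocity in meters per frame-step, floored at a small positive value."""
    v = config.sv_base - config.sv_gain * (_c(corr) + config.sv_offset) / config.sv_scale
    return max(config.sv_floor, v)


def map_parameters(
    state: AnxietyState, corr, config: ControllerConfig = DEFAULT_CONFIG
) -> StimulusParams:
    """Evaluate all five mappings on the same correction (pure function).

    REST returns the all-zero bundle: no stimuli appear in the rest state.
    """
    if state.label is StateLabel.REST:
        return ZERO_PARAMS
    return StimulusParams(
        sgf=sgf(state.label, corr, config),
        sjf=sjf(corr, config),
        spu=spu(corr, config),
        ss=ss(corr, config),
        sv=sv(corr, config),
    )


def static_schedule(
    state: AnxietyState, config: ControllerConfig = DEFAULT_CONFIG
) -> StimulusParams:
    """Fixed parameters of the pre-recorded (control) protocol.

    The published control condition gives only a qualitative description
    (LOW: smaller, slower, fewer spiders; HIGH: bigger, faster, more).  It is
    realized here as the adaptive bundle frozen at on-target corrections:
    c = 0 for LOW and c = -0.1 for HIGH, which makes HIGH strictly stronger
    than LOW in every parameter.  The EDA stream never influences these.
    """
    if state.label is StateLabel.REST:
        return ZERO_PARAMS
    c = (
        config.static_correction_low
        if state.label is StateLabel.LOW
        else config.static_correction_high
    )
    return map_parameters(state, c, config)


@dataclass(frozen=True)
class PhasePlan:
    """Ordered (state, duration-seconds) phases of the 5-minute session.

    Default: 60 s REST baseline, then LOW / REST / HIGH / REST, 60 s each —
    300 s total, active states alternating with rest.
    """

    phases: Tuple[Tuple[AnxietyState, float], ...] = (
        (REST, 60.0),
        (LOW, 60.0),
        (REST, 60.0),
        (HIGH, 60.0),
        (REST, 60.0),
    )

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.phases)

    @property
    def boundaries(self) -> List[float]:
        """Cumulative phase start times, plus the final end time."""
        out, acc = [0.0], 0.0
        for _, d in self.phases:
            acc += d
            out.append(acc)
        return out

    def active_phases(self) -> List[Tuple[int, AnxietyState, float, float]]:
        """(index, state, start, end) of the non-REST phases."""
        out = []
        for i, ((state, _), start, end) in enumerate(
            zip(self.phases, self.boundaries[:-1], self.boundaries[1:])
        ):
            if state.label is not StateLabel.REST:
                out.append((i, state, start, end))
        return out


DEFAULT_PLAN = PhasePlan()


def phase_at(t: float, plan: PhasePlan = DEFAULT_PLAN) -> Tuple[int, AnxietyState]:
    """Phase index and state at time t; boundaries are half-open [start, end)."""
    if t < 0 or t >= plan.total_duration:
        raise ValueError(
            f"t={t} outside the plan's [0, {plan.total_duration}) range"
        )
    acc = 0.0
    for i, (state, d) in enumerate(plan.phases):
        acc += d
        if t < acc:
            return i, state
    raise AssertionError("unreachable")
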