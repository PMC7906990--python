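"""Synthetic psychophysiology: raw EDA responses to stimulus intensity.

No raw human traces are published for the protocol this package simulates,
so the closed loop is exercised against a mechanistic stand-in.  A latent
arousal a >= 0 integrates the (latency-delayed) stimulus intensity through a
first-order relaxation

    da/dt = (g * I(t - latency) - a) / tau,
    tau = tau_rise  while the drive exceeds a (onset),
          tau_recover otherwise (recovery, slower than onset),

and maps to normalized EDA through an exponential link y = exp(-a), which
keeps the output positive, equal to 1 at perfect rest, and able to fall far
below 0.5 without crossing zero.  Raw output is relaxed_eda * y corrupted by
i.i.d. multiplicative Gaussian noise, emitted at the sensor's 100 Hz.

Electrodermal reactions to a discrete stimulus appear within about
1.6-5.5 s of stimulus onset, which is the default latency range; recovery
is slower than onset, encoded by tau_recover > tau_rise.  Cohorts are
heterogeneous in sensitivity (log-normal gain) to emulate hard- and
easy-to-stimulate individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .signal_io import DEFAULT_RATE, EdaTrace

__all__ = [
    "ParticipantProfile",
    "ArousalState",
    "ParticipantSim",
    "respond",
    "make_cohort",
    "cohort_to_frame",
]

LATENCY_RANGE = (1.6, 5.5)  # s, physiological reaction-latency band


@dataclass(frozen=True)
class ParticipantProfile:
    """Parameters of one synthetic participant.

    relaxed_eda: baseline raw EDA, arbitrary positive units.
    sensitivity: arousal gain g (dimensionless); steady-state normalized EDA
        under constant intensity I is exp(-g*I).
    latency: stimulus-to-response delay, seconds.
    tau_rise / tau_recover: onset and recovery time constants, seconds;
        recovery is slower.
    noise_sd: SD of the multiplicative measurement noise (fraction).
    habituation: optional linear gain-decay rate (fraction of g lost per
        second of accumulated stimulation); 0 disables it.
    """

    relaxed_eda: float = 5.0
    sensitivity: float = 1.0
    latency: float = 3.0
    tau_rise: float = 2.0
    tau_recover: float = 8.0
    noise_sd: float = 0.02
    seed: int = 0
    habituation: float = 0.0

    def __post_init__(self) -> None:
        if self.relaxed_eda <= 0 or self.sensitivity < 0:
            raise ValueError("relaxed_eda must be positive, sensitivity >= 0")
        if self.tau_recover <= self.tau_rise:
            raise ValueError("recovery must be slower than onset")
        if not 0 <= self.noise_sd < 0.2:
            raise ValueError("noise_sd must be a small fraction")


@dataclass
class ArousalState:
    """Latent arousal; a = 0 at perfect rest, y = exp(-a) in (0, 1]."""

    a: float = 0.0

    @property
    def normalized(self) -> float:
        return math.exp(-self.a)


class ParticipantSim:
    """Stateful 100 Hz stepper shared by the offline and closed-loop paths."""

    def __init__(
        self,
        profile: ParticipantProfile,
        rate: float = DEFAULT_RATE,
        rng: Union[np.random.Generator, int, None] = None,
    ):
        self.profile = profile
        self.rate = rate
        self.dt = 1.0 / rate
        if rng is None:
            rng = profile.seed
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.state = ArousalState(0.0)
        self._delay_n = max(1, int(round(profile.latency * rate)))
        self._buffer = [0.0] * self._delay_n
        self._head = 0
        self._gain = profile.sensitivity
        self._exposure = 0.0

    def step(self, intensity: float) -> float:
        """Advance one sample; returns the raw EDA reading."""
        p = self.profile
        # delayed intensity via ring buffer
        delayed = self._buffer[self._head]
        self._buffer[self._head] = intensity
        self._head = (self._head + 1) % self._delay_n

        if p.habituation > 0.0 and delayed > 0.0:
            self._exposure += self.dt
            self._gain = p.sensitivity * max(
                0.0, 1.0 - p.habituation * self._exposure
            )
        drive = self._gain * delayed
        a = self.state.a
        tau = p.tau_rise if drive > a else p.tau_recover
        a += self.dt * (drive - a) / tau
        self.state.a = max(0.0, a)

        eps = self.rng.normal(0.0, p.noise_sd) if p.noise_sd > 0 else 0.0
        return p.relaxed_eda * math.exp(-self.state.a) * (1.0 + eps)


def respond(
    profile: ParticipantProfile,
    intensity: Sequence[float],
    frame_rate: float = 60.0,
    rate: float = DEFAULT_RATE,
) -> EdaTrace:
    """Simulate the raw EDA trace in response to an intensity signal.

    ``intensity`` is sampled at ``frame_rate``; it is linearly resampled to
    the sensor rate (100 Hz) and pushed through the arousal stepper.
    """
    intensity = np.asarray(intensity, dtype=float)
    duration = intensity.size / frame_rate
    n_out = int(round(duration * rate))
    t_out = np.arange(n_out) / rate
    t_in = np.arange(intensity.size) / frame_rate
    resampled = np.interp(t_out, t_in, intensity)

    sim = ParticipantSim(profile, rate=rate)
    values = np.empty(n_out)
    for i in range(n_out):
        values[i] = sim.step(resampled[i])
    return EdaTrace.from_values(values, rate=rate)


def make_cohort(
    n: int,
    seed: int = 0,
    sensitivity_median: float = 1.0,
    sensitivity_sd: float = 0.4,
    latency_range: tuple = LATENCY_RANGE,
    relaxed_range: tuple = (2.0, 8.0),
    noise_sd: float = 0.02,
    tau_rise: float = 2.0,
    tau_recover: float = 8.0,
) -> List[ParticipantProfile]:
    """Draw a deterministic heterogeneous cohort.

    Sensitivity is log-normal (median ``sensitivity_median``, log-SD
    ``sensitivity_sd``) so the cohort spans hard- and easy-to-stimulate
    participants; latency is uniform on the physiological 1.6-5.5 s band;
    baseline raw EDA is uniform on a positive arbitrary-unit range.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        g = float(np.exp(np.log(sensitivity_median) + sensitivity_sd * rng.standard_normal()))
        lat = float(rng.uniform(*latency_range))
        relaxed = float(rng.uniform(*relaxed_range))
        profiles.append(
            ParticipantProfile(
                relaxed_eda=relaxed,
                sensitivity=g,
                latency=lat,
                tau_rise=tau_rise,
                tau_recover=tau_recover,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return profiles


def cohort_to_frame(cohort: Sequence[ParticipantProfile]) -> pd.DataFrame:
    """Profiles as a DataFrame (exportable to CSV for reproducibility)."""
    return pd.DataFrame([p.__dict__ for p in cohort])
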