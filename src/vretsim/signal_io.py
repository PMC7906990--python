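"""Electrodermal activity (EDA) traces: reading, writing, baseline, normalization.

The EDA sensor reports the voltage-response difference between two finger
electrodes at a uniform 100 Hz.  Anxiety raises sweat-gland activity, which
raises skin conductance and *lowers* the measured value; all downstream logic
therefore works on the normalized signal ``raw / relaxed``, which sits near
1.0 at rest and falls toward 0 with rising arousal.

The "Relaxed EDA value" is the arithmetic mean of the first stimulus-free
minute.  The session proper only starts once the incoming signal has settled
to within a tolerance band (default +/-8%) around that mean for a sustained
run of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "EdaSample",
    "EdaTrace",
    "BaselineEstimate",
    "TraceError",
    "TraceParseError",
    "acquire_baseline",
    "normalize",
    "read_trace",
    "write_trace",
    "write_log",
    "read_log",
]

DEFAULT_RATE = 100.0  # Hz, the sensor's transmission rate


class TraceError(ValueError):
    """Invalid trace content (non-positive values, bad spacing, too short)."""


class TraceParseError(TraceError):
    """Malformed trace file; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass(frozen=True)
class EdaSample:
    """One raw EDA reading.

    t is seconds from session start; value is the raw voltage-response
    difference in arbitrary positive units.
    """

    t: float
    value: float


@dataclass
class EdaTrace:
    """Uniformly sampled raw EDA signal.

    Stored internally as numpy arrays; ``samples`` iterates
    :class:`EdaSample` views for convenience.
    """

    t: np.ndarray
    values: np.ndarray
    rate: float = DEFAULT_RATE

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape or self.t.ndim != 1:
            raise TraceError("t and values must be 1-D arrays of equal length")
        if self.t.size:
            if self.t[0] < 0:
                raise TraceError("timestamps must be non-negative")
            if np.any(self.values <= 0):
                raise TraceError("EDA values must be strictly positive")
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise TraceError("timestamps must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.rate, rtol=0, atol=1e-6):
                raise TraceError(
                    f"sample spacing must be uniform at 1/{self.rate} s"
                )

    @classmethod
    def from_values(
        cls, values: Sequence[float], rate: float = DEFAULT_RATE, t0: float = 0.0
    ) -> "EdaTrace":
        values = np.asarray(values, dtype=float)
        t = t0 + np.arange(values.size) / rate
        return cls(t=t, values=values, rate=rate)

    @property
    def samples(self) -> Iterator[EdaSample]:
        return (EdaSample(float(a), float(b)) for a, b in zip(self.t, self.values))

    @property
    def duration(self) -> float:
        """Covered time span in seconds (n samples at rate r cover n/r s)."""
        return self.t.size / self.rate

    def __len__(self) -> int:
        return self.t.size

    def segment(self, start: float, stop: float) -> np.ndarray:
        """Values with start <= t < stop."""
        mask = (self.t >= start) & (self.t < stop)
        return self.values[mask]


@dataclass(frozen=True)
class BaselineEstimate:
    """Relaxed-EDA baseline from the stimulus-free first minute.

    relaxed_value: mean raw EDA over [0, window_duration).
    converged_at: first time at which the signal has stayed inside the
        tolerance band for the required hold run, or None if it never did.
    """

    relaxed_value: float
    converged_at: Optional[float]
    window_duration: float = 60.0

    @property
    def converged(self) -> bool:
        return self.converged_at is not None


def acquire_baseline(
    trace: EdaTrace,
    window: float = 60.0,
    tolerance: float = 0.08,
    hold: int = 100,
) -> BaselineEstimate:
    """Estimate the Relaxed EDA value and the convergence instant.

    The baseline is the arithmetic mean of all samples in ``[0, window)``.
    Convergence is declared at the first time ``>= window`` by which ``hold``
    consecutive samples have all lain within ``relaxed * (1 +/- tolerance)``;
    the reported instant is the time the hold run completes (run start +
    hold/rate).  With the defaults (hold=100 at 100 Hz) this demands one full
    in-band second, which makes the criterion robust to single-sample noise.
    """
    if not 0.0 < tolerance < 1.0:
        raise ValueError("tolerance must lie in (0, 1)")
    if hold < 1:
        raise ValueError("hold must be >= 1")
    if trace.duration < window:
        raise TraceError(
            f"trace covers {trace.duration:.2f} s, shorter than the "
            f"{window:.0f} s baseline window"
        )
    n_window = int(round(window * trace.rate))
    window_vals = trace.values[:n_window]
    relaxed = float(window_vals.mean())

    lo, hi = relaxed * (1.0 - tolerance), relaxed * (1.0 + tolerance)
    post = trace.values[n_window:]
    in_band = (post >= lo) & (post <= hi)
    converged_at: Optional[float] = None
    run = 0
    for i, ok in enumerate(in_band):
        run = run + 1 if ok else 0
        if run >= hold:
            start_idx = i - hold + 1
            converged_at = window + start_idx / trace.rate + hold / trace.rate
            break
    return BaselineEstimate(
        relaxed_value=relaxed, converged_at=converged_at, window_duration=window
    )


def normalize(raw: float, relaxed_value: float) -> float:
    """Normalized EDA: the raw reading divided by the Relaxed EDA value.

    Deliberately *not* clipped to [0, 1]: values slightly above 1 occur when
    the user is calmer than at baseline and must be preserved.
    """
    if raw <= 0 or relaxed_value <= 0:
        raise TraceError("EDA values must be strictly positive")
    return raw / relaxed_value


# ---------------------------------------------------------------------------
# file formats


def read_trace(path: Union[str, Path], rate: float = DEFAULT_RATE) -> EdaTrace:
    """Read a trace CSV with header ``t,value``."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
    cols = [c.strip() for c in header.split(",")]
    if cols[:2] != ["t", "value"]:
        raise TraceParseError(f"expected header 't,value', got {header!r}", line=1)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas reports its own line numbers
        raise TraceParseError(str(exc)) from exc
    for col in ("t", "value"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()]
        if len(bad):
            raise TraceParseError(
                f"non-numeric or missing {col}", line=int(bad[0]) + 2
            )
        df[col] = numeric
    return EdaTrace(t=df["t"].to_numpy(), values=df["value"].to_numpy(), rate=rate)


def write_trace(trace: EdaTrace, path: Union[str, Path]) -> None:
    """Write a trace CSV (full float precision, round-trips exactly)."""
    df = pd.DataFrame({"t": trace.t, "value": trace.values})
    df.to_csv(path, index=False, float_format="%.10g")


#: Per-tick session-log schema (one record per controller tick).
LOG_FIELDS = (
    "t",
    "raw",
    "normalized",
    "phase",
    "state",
    "correction",
    "sgf",
    "sjf",
    "spu",
    "ss",
    "sv",
    "active_spiders",
    "intensity",
)


def write_log(records, path: Union[str, Path]) -> None:
    """Write per-tick session records to CSV (``.jsonl`` writes JSON lines).

    ``records`` is a DataFrame or an iterable of mappings with the
    :data:`LOG_FIELDS` schema.
    """
    path = Path(path)
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if path.suffix == ".jsonl":
        df.to_json(path, orient="records", lines=True)
    else:
        df.to_csv(path, index=False, float_format="%.10g")


def read_log(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".jsonl":
        return pd.read_json(path, orient="records", lines=True)
    return pd.read_csv(path)
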