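"""Per-state session metrics, group summaries, and comparison statistics.

For each 60 s active-state window the normalized EDA trace is scored
sample-by-sample against the desired band [lo, hi]:

    State Maintenance Duration  time with lo <= y <= hi  (inside the band)
    Less Anxious Duration       time with y > hi         (above the band)
    More Anxious Duration       time with y < lo         (below the band)
    State Entrance Time         time of the first in-band sample
    Recovery Duration           time from the start of the following rest
                                window until y first re-enters the rest
                                band (y >= 0.92)

The three duration metrics partition the window, so they sum to the window
length to within one sample.  Entrance counts the first in-band sample
regardless of approach direction (Less Anxious Duration therefore includes
the entrance time).  Recovery is scored as first re-entry into the rest band
rather than an exact return to 1.0, which is a measure-zero event under
noise.

Group summaries use the population (divisor-n) standard deviation: that is
the convention that reproduces the published per-column summary statistics
of the reference tables shipped as fixtures (e.g. SD 6.94 for the
experimental State-1 maintenance column, where the sample convention gives
7.13).
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .signal_io import DEFAULT_RATE

__all__ = [
    "StateWindowMetrics",
    "GroupSummary",
    "AnovaResult",
    "FixtureError",
    "window_metrics",
    "summarize",
    "one_way_anova",
    "pearson",
    "load_fixture_tables",
    "fixture_frames",
    "METRIC_NAMES",
]

REST_BAND_LOW = 0.92  # lower edge of the rest band used for recovery

METRIC_NAMES = (
    "maintenance",
    "less_anxious",
    "more_anxious",
    "entrance_time",
    "recovery_duration",
)


@dataclass(frozen=True)
class StateWindowMetrics:
    """The five per-state metrics, in seconds.

    entrance_time is None if the band was never reached; recovery_duration
    is None if no following rest segment was given or the rest band was
    never re-entered.
    """

    maintenance: float
    less_anxious: float
    more_anxious: float
    entrance_time: Optional[float]
    recovery_duration: Optional[float]

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


@dataclass(frozen=True)
class GroupSummary:
    """Mean, population SD, and mean occupancy (% of the window)."""

    mean: float
    sd: float
    occupancy_percent: float


@dataclass(frozen=True)
class AnovaResult:
    """Two-group one-way ANOVA: F = MS_between / MS_within, df (1, n-2)."""

    F: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False  # zero within-group variance


class FixtureError(RuntimeError):
    """Packaged fixture table missing or corrupted."""


def window_metrics(
    segment: np.ndarray,
    band: Tuple[float, float],
    rest_segment: Optional[np.ndarray] = None,
    rate: float = DEFAULT_RATE,
    rest_band_low: float = REST_BAND_LOW,
) -> StateWindowMetrics:
    """Score one uniformly sampled normalized-EDA state window.

    ``segment`` holds the normalized values of the active-state window,
    ``rest_segment`` (optional) those of the immediately following rest
    window, used for the recovery metric.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("empty state window")
    lo, hi = band
    if not lo < hi:
        raise ValueError("band must satisfy lo < hi")

    inside = (segment >= lo) & (segment <= hi)
    maintenance = inside.sum() / rate
    less = (segment > hi).sum() / rate
    more = (segment < lo).sum() / rate

    entrance: Optional[float] = None
    hits = np.nonzero(inside)[0]
    if hits.size:
        entrance = hits[0] / rate

    recovery: Optional[float] = None
    if rest_segment is not None:
        rest_segment = np.asarray(rest_segment, dtype=float)
        back = np.nonzero(rest_segment >= rest_band_low)[0]
        if back.size:
            recovery = back[0] / rate

    return StateWindowMetrics(
        maintenance=maintenance,
        less_anxious=less,
        more_anxious=more,
        entrance_time=entrance,
        recovery_duration=recovery,
    )


def summarize(values: Sequence[float], window: float = 60.0) -> GroupSummary:
    """Mean, population SD, and occupancy percentage of a metric column."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("empty value list")
    mean = float(values.mean())
    return GroupSummary(
        mean=mean,
        sd=float(values.std(ddof=0)),
        occupancy_percent=100.0 * mean / window,
    )


def one_way_anova(group_a: Sequence[float], group_b: Sequence[float]) -> AnovaResult:
    """Two-group one-way ANOVA (scipy-backed)."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    df_b, df_w = 1, a.size + b.size - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return AnovaResult(0.0, df_b, df_w, 1.0, degenerate=True)
        return AnovaResult(float("inf"), df_b, df_w, 0.0, degenerate=True)
    F, p = stats.f_oneway(a, b)
    return AnovaResult(float(F), df_b, df_w, float(p))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# packaged reference tables (per-participant session metrics of the two
# 18-person groups, one row per participant, State-1 then State-2 columns)

_FIXTURES = {
    "experimental": (
        "experimental_group.csv",
        "01132a6bee9a0baf4ab1b97248a60a3bb56dfae7efda5192f593d132b683c7fa",
    ),
    "control": (
        "control_group.csv",
        "5aa37b5ca5cfa8f2650f46fa3db2e05192437d654ad5207ae7021bfa81dcf689",
    ),
}


def _read_fixture(name: str) -> pd.DataFrame:
    fname, digest = _FIXTURES[name]
    ref = resources.files("vretsim").joinpath("data", fname)
    try:
        raw = ref.read_bytes()
    except FileNotFoundError as exc:
        raise FixtureError(f"missing fixture table {fname}") from exc
    found = hashlib.sha256(raw).hexdigest()
    if found != digest:
        raise FixtureError(
            f"fixture {fname} corrupted: sha256 {found} != expected {digest}"
        )
    return pd.read_csv(io.BytesIO(raw))


def fixture_frames() -> Dict[str, pd.DataFrame]:
    """The two packaged tables in their wide (published) column layout."""
    return {name: _read_fixture(name) for name in _FIXTURES}


def load_fixture_tables() -> pd.DataFrame:
    """Long-form fixture records: 18 participants x 2 groups x 2 states.

    Columns: group, participant, state (LOW/HIGH), then the five metrics.
    Raises :class:`FixtureError` on a checksum mismatch.
    """
    rows = []
    for group, df in fixture_frames().items():
        for _, r in df.iterrows():
            for state, prefix in (("LOW", "state1"), ("HIGH", "state2")):
                rows.append(
                    {
                        "group": group,
                        "participant": int(r["participant"]),
                        "state": state,
                        "maintenance": r[f"{prefix}_maintenance"],
                        "less_anxious": r[f"{prefix}_less_anxious"],
                        "more_anxious": r[f"{prefix}_more_anxious"],
                        "entrance_time": r[f"{prefix}_entrance_time"],
                        "recovery_duration": r[f"{prefix}_recovery_duration"],
                    }
                )
    return pd.DataFrame(rows)
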