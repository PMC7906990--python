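"""Full closed-loop sessions and adaptive-vs-static cohort experiments.

A session reproduces the five-phase protocol: a one-minute stimulus-free
rest in which the Relaxed EDA baseline is acquired (plus however long the
signal needs to settle into the +/-8% band), then LOW / REST / HIGH / REST
minutes.  In *adaptive* mode the controller recomputes the correction and
the five stimulus parameters at every 100 Hz EDA sample and drives the
spider arena with them; in *static* mode the arena follows the fixed
pre-recorded schedule and the EDA stream is recorded but never fed back.

The cohort experiment runs every synthetic participant under both modes
with identical seeds — a paired design, which is stricter than the original
two-independent-groups comparison and is what the per-participant tables
and the two-group ANOVA summarize.  Sessions are fully deterministic given
their seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .arena import Arena, IntensityWeights, RoomLayout
from .controller import (
    DEFAULT_CONFIG,
    ControllerConfig,
    PhasePlan,
    StateLabel,
    StimulusParams,
    map_parameters,
    sgf as _sgf,
    sjf as _sjf,
    spu as _spu,
    ss as _ss,
    sv as _sv,
    static_schedule,
)
from .metrics import (
    AnovaResult,
    StateWindowMetrics,
    one_way_anova,
    summarize,
    window_metrics,
)
from .participant import ParticipantProfile, ParticipantSim
from .signal_io import LOG_FIELDS, BaselineEstimate, EdaTrace

__all__ = [
    "SessionConfig",
    "SessionLog",
    "CohortResult",
    "BaselineConvergenceError",
    "calibrate_intensity_scale",
    "run_session",
    "run_cohort",
    "plot_session",
]


class BaselineConvergenceError(RuntimeError):
    """The signal never settled into the baseline tolerance band."""


def calibrate_intensity_scale(
    controller: ControllerConfig = DEFAULT_CONFIG,
    weights: Optional[IntensityWeights] = None,
    layout: Optional[RoomLayout] = None,
    frame_rate: float = 60.0,
    divisor: float = 100.0,
    velocity_scale: float = 5.0,
) -> float:
    """Intensity normalization matching the actuator scale to the arousal scale.

    The arena's intensity scalar and the participant model are both invented
    plumbing, and only the *product* of stimulus intensity and participant
    gain is observable, so one overall scale is free.  It is calibrated, not
    guessed: the normalization is chosen so that, at the on-target correction
    (c = -0.05, the middle of the published on-target band), the steady-state
    arousal of a median-sensitivity participant equals the arousal of the
    desired band's center.  Steady-state unscaled intensity is spawn rate
    (sgf/divisor) x mean route residence time x mean per-spider
    contribution, all computed from the room geometry, the intensity
    weights, and the stimulus mappings at c = -0.05; the final scale is the
    geometric mean of the LOW and HIGH solutions.  Everything here is
    closed-form in the model constants; no simulation output enters the
    calibration.
    """
    from .controller import HIGH, LOW, sgf, sjf, spu, ss, sv

    weights = weights or IntensityWeights()
    layout = layout or RoomLayout()
    c_on = -0.05
    p_detour, vel = spu(c_on, controller), sv(c_on, controller)
    size, jump = ss(c_on, controller), sjf(c_on, controller)
    diag = layout.diagonal

    # route-length and route-averaged proximity, enumerated over the
    # 4 x 4 x {detour, direct} equally likely routes
    total_w = total_len = total_prox = 0.0
    for g in range(4):
        for e in range(4):
            for detour, w in ((False, 1 - p_detour), (True, p_detour)):
                pts = [layout.generation_points[g],
                       layout.destination_assignment_points[g]]
                if detour:
                    pts.append(layout.user_position)
                pts += [layout.gathering_points[e], layout.exit_points[e]]
                length = prox = 0.0
                for a, b in zip(pts[:-1], pts[1:]):
                    seg = float(np.linalg.norm(b - a))
                    ts = np.linspace(0.0, 1.0, 50)
                    line = a[None, :] + (b - a)[None, :] * ts[:, None]
                    d = np.linalg.norm(line - layout.user_position, axis=1)
                    length += seg
                    prox += seg * float(np.maximum(0.0, 1.0 - d / diag).mean())
                total_w += w
                total_len += w * length
                total_prox += w * prox / length
    mean_len = total_len / total_w
    mean_prox = total_prox / total_w

    residence = mean_len / (vel * velocity_scale * frame_rate)
    kappa = (
        weights.w_presence
        + weights.w_size * size
        + weights.w_velocity * vel / weights.v_ref
        + weights.w_jump * jump / weights.j_ref
        + weights.w_proximity * mean_prox
    )
    scales = []
    for state in (LOW, HIGH):
        y_center = 0.5 * (state.band_low + state.band_high)
        a_target = -math.log(y_center)
        rate = sgf(state.label, c_on, controller) / divisor
        scales.append(a_target / (rate * residence * kappa))
    return float(np.exp(np.mean(np.log(scales))))


@dataclass(frozen=True)
class SessionConfig:
    """Everything one session needs besides the participant profile."""

    mode: str = "adaptive"  # "adaptive" | "static"
    plan: PhasePlan = field(default_factory=PhasePlan)
    controller: ControllerConfig = DEFAULT_CONFIG
    weights: IntensityWeights = field(default_factory=IntensityWeights)
    frame_rate: float = 60.0
    eda_rate: float = 100.0
    divisor: float = 100.0  # spawn-rate conversion: sgf/divisor spiders per s
    velocity_scale: float = 5.0  # published velocity units -> simulated m/frame
    #: global intensity normalization; None uses the arousal-matched
    #: calibration of :func:`calibrate_intensity_scale`
    intensity_scale: Optional[float] = None
    baseline_window: float = 60.0
    baseline_tolerance: float = 0.08
    baseline_hold: int = 100
    baseline_max_wait: float = 60.0
    seed: int = 0
    abort_at: Optional[float] = None  # session clock, s (clinician abort)
    log_path: Optional[Union[str, Path]] = None  # crash-safe per-tick CSV
    record_events: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("adaptive", "static"):
            raise ValueError("mode must be 'adaptive' or 'static'")


@dataclass
class SessionLog:
    """Everything a finished (or aborted) session produced."""

    mode: str
    baseline: BaselineEstimate
    ticks: pd.DataFrame  # one record per 100 Hz controller tick
    trace: EdaTrace  # the raw EDA trace actually "recorded"
    metrics: Dict[StateLabel, StateWindowMetrics]
    spiders_spawned: int
    spiders_exited: int
    spiders_active: int
    events: List[tuple]
    aborted: bool = False

    @property
    def duration(self) -> float:
        if not len(self.ticks):
            return 0.0
        return float(self.ticks["t"].iloc[-1]) + 1.0 / self.trace.rate


_STATE_CODE = {StateLabel.REST: 0, StateLabel.LOW: 1, StateLabel.HIGH: 2}

_scale_cache: Dict[tuple, float] = {}


def _default_scale(
    cc: ControllerConfig,
    weights: IntensityWeights,
    frame_rate: float,
    divisor: float,
    velocity_scale: float,
) -> float:
    key = (
        id(cc) if cc is not DEFAULT_CONFIG else "default",
        weights,
        frame_rate,
        divisor,
        velocity_scale,
    )
    if key not in _scale_cache:
        _scale_cache[key] = calibrate_intensity_scale(
            cc, weights, frame_rate=frame_rate, divisor=divisor,
            velocity_scale=velocity_scale,
        )
    return _scale_cache[key]


def run_session(profile: ParticipantProfile, config: SessionConfig) -> SessionLog:
    """Run one full closed-loop (or static) session.

    Phase timing starts at the baseline convergence instant: samples taken
    while waiting for convergence (after the one-minute window) belong to no
    phase and are excluded from all metrics.  Raises
    :class:`BaselineConvergenceError` if the signal never settles within
    ``baseline_max_wait`` seconds after the window.
    """
    cc = config.controller
    rate = config.eda_rate
    dt = 1.0 / rate
    ss_seq = np.random.SeedSequence([config.seed, profile.seed & 0x7FFFFFFF])
    noise_ss, arena_ss = ss_seq.spawn(2)
    part = ParticipantSim(profile, rate=rate, rng=np.random.default_rng(noise_ss))
    scale = config.intensity_scale
    if scale is None:
        scale = _default_scale(
            cc, config.weights, config.frame_rate, config.divisor,
            config.velocity_scale,
        )
    arena = Arena(
        weights=config.weights,
        frame_rate=config.frame_rate,
        divisor=config.divisor,
        intensity_scale=scale,
        velocity_scale=config.velocity_scale,
        rng=np.random.default_rng(arena_ss),
        record_events=config.record_events,
    )

    plan = config.plan
    n_base = int(round(config.baseline_window * rate))
    n_wait_max = int(round(config.baseline_max_wait * rate))
    main_duration = plan.total_duration - config.baseline_window
    n_main = int(round(main_duration * rate))
    n_max = n_base + n_wait_max + n_main

    # preallocated per-tick log columns
    cols = {k: np.zeros(n_max) for k in LOG_FIELDS if k not in ("phase", "state")}
    phase_col = np.zeros(n_max, dtype=np.int64)
    state_col = np.zeros(n_max, dtype=np.int64)

    logfile = None
    if config.log_path is not None:
        logfile = open(config.log_path, "w", buffering=1)  # line-buffered
        logfile.write(",".join(LOG_FIELDS) + "\n")

    def emit(i, t, raw, y, phase, state, c, params, active, intensity):
        cols["t"][i] = t
        cols["raw"][i] = raw
        cols["normalized"][i] = y
        phase_col[i] = phase
        state_col[i] = _STATE_CODE[state.label]
        cols["correction"][i] = c
        (
            cols["sgf"][i],
            cols["sjf"][i],
            cols["spu"][i],
            cols["ss"][i],
            cols["sv"][i],
        ) = params
        cols["active_spiders"][i] = active
        cols["intensity"][i] = intensity
        if logfile is not None:
            logfile.write(
                f"{t:.2f},{raw:.6g},{y:.6g},{phase},{state.label.value},{c:.6g},"
                f"{params[0]:.6g},{params[1]:.6g},{params[2]:.6g},"
                f"{params[3]:.6g},{params[4]:.6g},{active},{intensity:.6g}\n"
            )

    zero = (0.0, 0.0, 0.0, 0.0, 0.0)
    rest_state = plan.phases[0][0]

    # ---- phase zero: baseline window -------------------------------------
    i = 0
    for k in range(n_base):
        raw = part.step(0.0)
        emit(i, k * dt, raw, 1.0, 0, rest_state, 0.0, zero, 0, 0.0)
        i += 1
    relaxed = float(cols["raw"][:n_base].mean())
    # normalized values during the window, in hindsight
    cols["normalized"][:n_base] = cols["raw"][:n_base] / relaxed

    # ---- convergence wait: hold consecutive in-band samples ---------------
    lo = relaxed * (1.0 - config.baseline_tolerance)
    hi = relaxed * (1.0 + config.baseline_tolerance)
    run = 0
    converged_at = None
    for k in range(n_wait_max):
        raw = part.step(0.0)
        t = (n_base + k) * dt
        emit(i, t, raw, raw / relaxed, 0, rest_state, 0.0, zero, 0, 0.0)
        i += 1
        run = run + 1 if lo <= raw <= hi else 0
        if run >= config.baseline_hold:
            converged_at = t + dt
            break
    if converged_at is None:
        if logfile is not None:
            logfile.close()
        raise BaselineConvergenceError(
            f"no {config.baseline_hold}-sample run within +/-"
            f"{config.baseline_tolerance:.0%} of the relaxed value "
            f"{relaxed:.4g} in {config.baseline_max_wait:.0f} s"
        )
    baseline = BaselineEstimate(
        relaxed_value=relaxed,
        converged_at=converged_at,
        window_duration=config.baseline_window,
    )

    # ---- phases 1..n: the plan clock resumes at the window's end ----------
    adaptive = config.mode == "adaptive"
    static_bundles = {
        st.label: static_schedule(st, cc).astuple()
        for st, _ in plan.phases
    }
    boundaries = plan.boundaries
    frame_per_tick = config.frame_rate / rate
    frame_acc = 0.0
    intensity = 0.0
    phase_idx = 0
    current_state = rest_state
    params_obj: Optional[StimulusParams] = None
    aborted = False
    t_wall = converged_at  # wall clock of the session log

    for k in range(n_main):
        t_plan = config.baseline_window + k * dt
        t_wall = converged_at + k * dt
        if config.abort_at is not None and t_wall >= config.abort_at:
            aborted = True
            break
        # phase lookup (half-open [start, end) boundaries)
        while t_plan >= boundaries[phase_idx + 1] - 1e-9:
            phase_idx += 1
            new_state = plan.phases[phase_idx][0]
            if new_state.label is StateLabel.REST:
                arena.clear()
                intensity = 0.0
            current_state = new_state
            params_obj = None
        state = current_state

        raw = part.step(intensity)
        y = raw / relaxed

        if state.label is StateLabel.REST:
            c = 0.0
            params = zero
            params_obj = None
        else:
            c = state.representative - y
            if adaptive:
                params = (
                    _sgf(state.label, c, cc),
                    _sjf(c, cc),
                    _spu(c, cc),
                    _ss(c, cc),
                    _sv(c, cc),
                )
                params_obj = StimulusParams(*params)
            else:
                params = static_bundles[state.label]
                if params_obj is None:
                    params_obj = StimulusParams(*params)

        frame_acc += frame_per_tick
        while frame_acc >= 1.0:
            frame_acc -= 1.0
            if params_obj is not None:
                intensity = arena.step(params_obj).value
            else:
                # rest: nothing spawns and the room is empty
                intensity = 0.0

        emit(i, t_wall, raw, y, phase_idx, state, c, params, arena.active, intensity)
        i += 1

    if logfile is not None:
        logfile.close()

    ticks = pd.DataFrame(
        {
            "t": cols["t"][:i],
            "raw": cols["raw"][:i],
            "normalized": cols["normalized"][:i],
            "phase": phase_col[:i],
            "state": state_col[:i],
            "correction": cols["correction"][:i],
            "sgf": cols["sgf"][:i],
            "sjf": cols["sjf"][:i],
            "spu": cols["spu"][:i],
            "ss": cols["ss"][:i],
            "sv": cols["sv"][:i],
            "active_spiders": cols["active_spiders"][:i].astype(int),
            "intensity": cols["intensity"][:i],
        }
    )
    trace = EdaTrace(
        t=np.arange(i) * dt, values=np.maximum(cols["raw"][:i], 1e-12), rate=rate
    )

    # ---- per-state metrics -------------------------------------------------
    session_metrics: Dict[StateLabel, StateWindowMetrics] = {}
    if not aborted:
        y_main = cols["normalized"][i - n_main : i]
        for p_idx, st, start, end in plan.active_phases():
            a = int(round((start - config.baseline_window) * rate))
            b = int(round((end - config.baseline_window) * rate))
            rest_a, rest_b = b, min(
                b + int(round(60.0 * rate)), y_main.size
            )
            rest_seg = y_main[rest_a:rest_b] if rest_b > rest_a else None
            session_metrics[st.label] = window_metrics(
                y_main[a:b], st.band, rest_segment=rest_seg, rate=rate
            )

    return SessionLog(
        mode=config.mode,
        baseline=baseline,
        ticks=ticks,
        trace=trace,
        metrics=session_metrics,
        spiders_spawned=arena.spawned,
        spiders_exited=arena.exited,
        spiders_active=arena.active,
        events=list(arena.events),
        aborted=aborted,
    )


# ---------------------------------------------------------------------------
# cohort experiments


@dataclass
class CohortResult:
    """Paired adaptive-vs-static cohort outcome.

    ``tables`` maps mode -> wide per-participant DataFrame shaped like the
    published per-group tables (five metrics per state); ``summary`` holds
    mean / population SD / occupancy per mode, state, and metric; ``anova``
    compares maintenance durations between modes per state.
    """

    tables: Dict[str, pd.DataFrame]
    summary: pd.DataFrame
    anova: Dict[StateLabel, AnovaResult]

    def occupancy(self, mode: str, state: StateLabel) -> float:
        sel = self.summary
        row = sel[
            (sel["mode"] == mode)
            & (sel["state"] == state.value)
            & (sel["metric"] == "maintenance")
        ]
        return float(row["occupancy_percent"].iloc[0])


def _metrics_row(log: SessionLog) -> Dict[str, float]:
    row: Dict[str, float] = {}
    for state, prefix in ((StateLabel.LOW, "state1"), (StateLabel.HIGH, "state2")):
        m = log.metrics[state]
        row[f"{prefix}_maintenance"] = m.maintenance
        row[f"{prefix}_less_anxious"] = m.less_anxious
        row[f"{prefix}_more_anxious"] = m.more_anxious
        row[f"{prefix}_entrance_time"] = (
            math.nan if m.entrance_time is None else m.entrance_time
        )
        row[f"{prefix}_recovery_duration"] = (
            math.nan if m.recovery_duration is None else m.recovery_duration
        )
    return row


def run_cohort(
    cohort: Sequence[ParticipantProfile],
    config: SessionConfig,
    window: float = 60.0,
) -> CohortResult:
    """Run every profile under both modes (paired design) and summarize.

    ``config.mode`` is ignored; both an adaptive and a static session are
    run per participant with identical seeds, so the two protocol arms see
    the same participant physiology and the same random draws.
    """
    if len(cohort) < 2:
        raise ValueError("cohort needs at least 2 participants")
    tables: Dict[str, pd.DataFrame] = {}
    for mode in ("adaptive", "static"):
        rows = []
        for j, profile in enumerate(cohort, start=1):
            log = run_session(profile, replace(config, mode=mode))
            rows.append({"participant": j, **_metrics_row(log)})
        tables[mode] = pd.DataFrame(rows)

    summary_rows = []
    for mode, df in tables.items():
        for state, prefix in ((StateLabel.LOW, "state1"), (StateLabel.HIGH, "state2")):
            for metric in (
                "maintenance",
                "less_anxious",
                "more_anxious",
                "entrance_time",
                "recovery_duration",
            ):
                vals = df[f"{prefix}_{metric}"].dropna()
                if len(vals) == 0:
                    continue
                s = summarize(vals, window=window)
                summary_rows.append(
                    {
                        "mode": mode,
                        "state": state.value,
                        "metric": metric,
                        "mean": s.mean,
                        "sd": s.sd,
                        "occupancy_percent": s.occupancy_percent
                        if metric == "maintenance"
                        else math.nan,
                    }
                )
    summary = pd.DataFrame(summary_rows)

    anova = {
        state: one_way_anova(
            tables["adaptive"][f"{prefix}_maintenance"],
            tables["static"][f"{prefix}_maintenance"],
        )
        for state, prefix in ((StateLabel.LOW, "state1"), (StateLabel.HIGH, "state2"))
    }
    return CohortResult(tables=tables, summary=summary, anova=anova)


def plot_session(log: SessionLog, path: Union[str, Path]) -> None:
    """Plot the normalized trace with desired/above/below band coloring.

    Green marks samples inside the desired band of the active state, red
    above it (less anxious), blue below it (more anxious); rest-phase
    samples are grey.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = log.ticks["t"].to_numpy()
    y = log.ticks["normalized"].to_numpy()
    state = log.ticks["state"].to_numpy()
    bands = {1: (0.70, 0.8), 2: (0.40, 0.5)}
    colors = np.full(t.shape, "grey", dtype=object)
    for code, (lo, hi) in bands.items():
        sel = state == code
        colors[sel & (y >= lo) & (y <= hi)] = "green"
        colors[sel & (y > hi)] = "red"
        colors[sel & (y < lo)] = "blue"
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.scatter(t, y, c=list(colors), s=1, linewidths=0)
    ax.set_xlabel("time [s]")
    ax.set_ylabel("normalized EDA")
    ax.set_ylim(0, 1.2)
    ax.set_title(f"{log.mode} session")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
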