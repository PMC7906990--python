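"""Discrete-time agent simulation of the spider room.

Spiders pop up behind an occluder at one of four generation points, walk a
straight line to a destination-assignment point (where their exit is fixed),
optionally detour under the user's chair, regroup at a gathering point near
their exit, and vanish at one of four occluded exit points.  Waypoint routing
is what keeps spiders from colliding, so no collision handling is simulated.

Geometry is not prescribed by the protocol the simulator reproduces — only
the route topology matters — so a 5 m x 5 m floor is used: generation points
at wall midpoints, exits at the corners, gathering points 0.5 m inside each
exit, destination-assignment points 0.5 m in front of each generation point,
user at the room center.  Velocities are meters per frame at the simulation
frame rate (default 60 fps), which makes an on-target spider cross the room
in a few seconds.

A scalar *stimulus intensity* summarises the scene for the synthetic
participant: each active spider contributes a weighted sum of its presence,
size, speed, jumping force, and proximity to the user.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Tuple, Union

import numpy as np

from .controller import StimulusParams

__all__ = [
    "Stage",
    "RoomLayout",
    "IntensityWeights",
    "Spider",
    "IntensitySample",
    "SpawnAccumulator",
    "Arena",
]


class Stage(str, enum.Enum):
    GENERATED = "GENERATED"
    TO_DESTINATION_POINT = "TO_DESTINATION_POINT"
    TO_USER = "TO_USER"
    TO_GATHERING = "TO_GATHERING"
    TO_EXIT = "TO_EXIT"
    EXITED = "EXITED"


def _default_layout_arrays():
    side = 5.0
    gen = np.array(
        [[side / 2, 0, 0], [side, side / 2, 0], [side / 2, side, 0], [0, side / 2, 0]]
    )
    center = np.array([side / 2, side / 2, 0.0])
    # destination-assignment points 0.5 m in front of each generation point
    to_center = center - gen
    dest = gen + 0.5 * to_center / np.linalg.norm(to_center, axis=1, keepdims=True)
    exits = np.array([[0, 0, 0], [side, 0, 0], [side, side, 0], [0, side, 0.0]])
    to_center_e = center - exits
    gather = exits + 0.5 * to_center_e / np.linalg.norm(
        to_center_e, axis=1, keepdims=True
    )
    return gen, dest, gather, exits, center


class RoomLayout:
    """Positions (meters, 3-vectors) of the routing waypoints and the user.

    Exactly four generation and four exit points; gathering points are
    per-exit.  Occluders at generation/exit points are conceptual only.
    """

    def __init__(
        self,
        generation_points: Optional[np.ndarray] = None,
        destination_assignment_points: Optional[np.ndarray] = None,
        gathering_points: Optional[np.ndarray] = None,
        exit_points: Optional[np.ndarray] = None,
        user_position: Optional[np.ndarray] = None,
    ):
        g, d, r, e, u = _default_layout_arrays()
        self.generation_points = np.asarray(
            generation_points if generation_points is not None else g, float
        )
        self.destination_assignment_points = np.asarray(
            destination_assignment_points
            if destination_assignment_points is not None
            else d,
            float,
        )
        self.gathering_points = np.asarray(
            gathering_points if gathering_points is not None else r, float
        )
        self.exit_points = np.asarray(
            exit_points if exit_points is not None else e, float
        )
        self.user_position = np.asarray(
            user_position if user_position is not None else u, float
        )
        if len(self.generation_points) != 4 or len(self.exit_points) != 4:
            raise ValueError("the room has exactly 4 generation and 4 exit points")

    @property
    def diagonal(self) -> float:
        span = self.exit_points.max(axis=0) - self.exit_points.min(axis=0)
        return float(np.linalg.norm(span))


@dataclass(frozen=True)
class IntensityWeights:
    """Weights of the per-spider intensity contribution.

    contribution = w_presence + w_size*size + w_velocity*(v/v_ref)
                 + w_jump*(jumping_force/j_ref) + w_proximity*proximity
    with proximity = max(0, 1 - distance_to_user/room_diagonal).
    v_ref/j_ref are the on-target (c = -0.1 .. 0) parameter extremes.
    """

    w_presence: float = 0.2
    w_size: float = 0.3
    w_velocity: float = 0.15
    w_jump: float = 0.15
    w_proximity: float = 0.2
    v_ref: float = 0.006
    j_ref: float = 0.049


@dataclass
class Spider:
    """Object view of one agent (used in event logs and tests)."""

    id: int
    spawned_at: float
    size: float
    velocity: float
    jumping_force: float
    detour: bool
    stage: Stage
    position: np.ndarray


class IntensitySample(NamedTuple):
    t: float
    value: float


class SpawnAccumulator:
    """Deterministic fractional-accumulator spawn policy.

    Each frame adds ``sgf / (divisor * frame_rate)`` to an accumulator and
    spawns on every unit crossing, so the expected spawn rate is
    ``sgf / divisor`` spiders per second and inter-spawn intervals are fully
    determined by the SGF history.  sgf = 0 spawns nothing.
    """

    def __init__(self, frame_rate: float = 60.0, divisor: float = 100.0):
        self.frame_rate = frame_rate
        self.divisor = divisor
        self.acc = 0.0

    def step(self, sgf: float) -> int:
        """Number of spiders to spawn this frame."""
        if sgf < 0:
            raise ValueError("sgf must be non-negative")
        if sgf == 0:
            return 0
        self.acc += sgf / (self.divisor * self.frame_rate)
        n = int(self.acc)
        self.acc -= n
        return n


# route stages in visiting order, detour inserts TO_USER before TO_GATHERING
_ROUTE_NO_DETOUR = (Stage.TO_DESTINATION_POINT, Stage.TO_GATHERING, Stage.TO_EXIT)
_ROUTE_DETOUR = (
    Stage.TO_DESTINATION_POINT,
    Stage.TO_USER,
    Stage.TO_GATHERING,
    Stage.TO_EXIT,
)


class Arena:
    """The spider-room world, stepped one frame at a time.

    State is kept in struct-of-arrays form so a frame is a handful of
    vectorized operations regardless of the number of active spiders.
    Determinism: identical seed and parameter history give an identical
    event log.
    """

    def __init__(
        self,
        layout: Optional[RoomLayout] = None,
        weights: Optional[IntensityWeights] = None,
        frame_rate: float = 60.0,
        divisor: float = 100.0,
        rng: Union[np.random.Generator, int, None] = 0,
        record_events: bool = False,
        intensity_scale: float = 1.0,
        velocity_scale: float = 5.0,
    ):
        self.layout = layout or RoomLayout()
        self.weights = weights or IntensityWeights()
        self.intensity_scale = intensity_scale
        #: conversion from the published velocity parameter (meters per
        #: frame-step) to simulated meters per frame.  The default makes an
        #: on-target spider cross the room in a few seconds, the behavior
        #: the protocol describes; at 1.0 the crossing would take ~17 s.
        self.velocity_scale = velocity_scale
        self.frame_rate = frame_rate
        self.spawner = SpawnAccumulator(frame_rate, divisor)
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.record_events = record_events
        self.events: List[tuple] = []

        self.t = 0.0
        self.spawned = 0
        self.exited = 0
        self._next_id = 0
        n = 0
        self._pos = np.empty((n, 3))
        self._route = np.empty((n, 4, 3))  # up to 4 waypoints after spawn
        self._route_len = np.empty(n, dtype=np.int64)
        self._leg = np.empty(n, dtype=np.int64)
        self._stages = np.empty((n, 4), dtype=object)
        self._vel = np.empty(n)
        self._size = np.empty(n)
        self._jf = np.empty(n)
        self._detour = np.empty(n, dtype=bool)
        self._ids = np.empty(n, dtype=np.int64)
        self._spawned_at = np.empty(n)
        self._diag = self.layout.diagonal

    # -- inspection --------------------------------------------------------

    @property
    def active(self) -> int:
        return self._pos.shape[0]

    def spiders(self) -> List[Spider]:
        out = []
        for i in range(self.active):
            leg = int(self._leg[i])
            stage = self._stages[i, min(leg, self._route_len[i] - 1)]
            out.append(
                Spider(
                    id=int(self._ids[i]),
                    spawned_at=float(self._spawned_at[i]),
                    size=float(self._size[i]),
                    velocity=float(self._vel[i]),
                    jumping_force=float(self._jf[i]),
                    detour=bool(self._detour[i]),
                    stage=Stage(stage),
                    position=self._pos[i].copy(),
                )
            )
        return out

    # -- dynamics ----------------------------------------------------------

    def _spawn(self, params: StimulusParams, n: int) -> None:
        lay = self.layout
        gen_idx = self.rng.integers(0, 4, size=n)
        exit_idx = self.rng.integers(0, 4, size=n)
        detour = self.rng.random(n) < params.spu

        pos = lay.generation_points[gen_idx]
        route = np.zeros((n, 4, 3))
        route_len = np.empty(n, dtype=np.int64)
        stages = np.empty((n, 4), dtype=object)
        for k in range(n):
            wp = [lay.destination_assignment_points[gen_idx[k]]]
            if detour[k]:
                wp.append(lay.user_position)
                names = _ROUTE_DETOUR
            else:
                names = _ROUTE_NO_DETOUR
            wp.append(lay.gathering_points[exit_idx[k]])
            wp.append(lay.exit_points[exit_idx[k]])
            route[k, : len(wp)] = wp
            route_len[k] = len(wp)
            stages[k, : len(names)] = names
        ids = self._next_id + np.arange(n)
        self._next_id += n
        self.spawned += n

        self._pos = np.concatenate([self._pos, pos])
        self._route = np.concatenate([self._route, route])
        self._route_len = np.concatenate([self._route_len, route_len])
        self._leg = np.concatenate([self._leg, np.zeros(n, dtype=np.int64)])
        self._stages = np.concatenate([self._stages, stages])
        self._vel = np.concatenate([self._vel, np.full(n, params.sv)])
        self._size = np.concatenate([self._size, np.full(n, params.ss)])
        self._jf = np.concatenate([self._jf, np.full(n, params.sjf)])
        self._detour = np.concatenate([self._detour, detour])
        self._ids = np.concatenate([self._ids, ids])
        self._spawned_at = np.concatenate([self._spawned_at, np.full(n, self.t)])
        if self.record_events:
            for k in range(n):
                self.events.append(
                    (
                        self.t,
                        int(ids[k]),
                        "spawn",
                        Stage.GENERATED.value,
                        tuple(pos[k]),
                        {
                            "size": params.ss,
                            "velocity": params.sv,
                            "jumping_force": params.sjf,
                            "detour": bool(detour[k]),
                        },
                    )
                )

    def _remove(self, mask: np.ndarray) -> None:
        keep = ~mask
        self._pos = self._pos[keep]
        self._route = self._route[keep]
        self._route_len = self._route_len[keep]
        self._leg = self._leg[keep]
        self._stages = self._stages[keep]
        self._vel = self._vel[keep]
        self._size = self._size[keep]
        self._jf = self._jf[keep]
        self._detour = self._detour[keep]
        self._ids = self._ids[keep]
        self._spawned_at = self._spawned_at[keep]

    def step(self, params: StimulusParams) -> IntensitySample:
        """Advance one frame (1/frame_rate s): spawn, move, retire, measure.

        Each active spider moves ``velocity`` meters along the straight line
        to its current waypoint; on arrival it snaps to the waypoint and
        advances to the next route stage; past the exit it is removed.
        A spider's own parameters are fixed at its spawn instant.
        """
        self.t += 1.0 / self.frame_rate
        n_new = self.spawner.step(params.sgf)
        if n_new:
            self._spawn(params, n_new)

        if self.active:
            idx = np.arange(self.active)
            target = self._route[idx, self._leg]
            delta = target - self._pos
            dist = np.linalg.norm(delta, axis=1)
            step_len = self._vel * self.velocity_scale
            arrive = dist <= step_len
            move = ~arrive & (dist > 0)
            if move.any():
                self._pos[move] += (
                    delta[move] / dist[move, None] * step_len[move, None]
                )
            if arrive.any():
                self._pos[arrive] = target[arrive]
                if self.record_events:
                    for i in np.nonzero(arrive)[0]:
                        leg = int(self._leg[i])
                        nxt = leg + 1
                        stage = (
                            Stage.EXITED
                            if nxt >= self._route_len[i]
                            else self._stages[i, nxt]
                        )
                        self.events.append(
                            (
                                self.t,
                                int(self._ids[i]),
                                "stage",
                                Stage(stage).value,
                                tuple(self._pos[i]),
                                None,
                            )
                        )
                self._leg[arrive] += 1
                done = self._leg >= self._route_len
                if done.any():
                    self.exited += int(done.sum())
                    self._remove(done)

        return self.intensity()

    def clear(self) -> int:
        """Remove every active spider immediately (stimulus-free rest phase).

        Cleared spiders count as exited so the spawned = exited + active
        conservation holds.  Returns the number removed.
        """
        n = self.active
        if n:
            if self.record_events:
                for i in range(n):
                    self.events.append(
                        (
                            self.t,
                            int(self._ids[i]),
                            "cleared",
                            Stage.EXITED.value,
                            tuple(self._pos[i]),
                            None,
                        )
                    )
            self.exited += n
            self._remove(np.ones(n, dtype=bool))
        return n

    def intensity(self) -> IntensitySample:
        """Scalar stimulus intensity: additive over active spiders.

        ``intensity_scale`` is a global normalization applied to the sum
        (default 1); the session layer calibrates it so the actuator scale
        matches the participant model's arousal scale.
        """
        if not self.active:
            return IntensitySample(self.t, 0.0)
        w = self.weights
        d_user = np.linalg.norm(self._pos - self.layout.user_position, axis=1)
        prox = np.maximum(0.0, 1.0 - d_user / self._diag)
        value = (
            self.active * w.w_presence
            + w.w_size * self._size.sum()
            + w.w_velocity * (self._vel / w.v_ref).sum()
            + w.w_jump * (self._jf / w.j_ref).sum()
            + w.w_proximity * prox.sum()
        )
        return IntensitySample(self.t, float(value) * self.intensity_scale)
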