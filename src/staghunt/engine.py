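"""Arena physics, ray geometry, capture logic, and the episode loop.

The world is an axis-aligned rectangle with solid walls.  Two wheeled
hunters (differential drive) and a fixed number of stationary prey, all
solid disks of one diameter, occupy it.  A prey is captured when at
least one hunter stays within catching distance for ``capture_steps``
consecutive steps; the hunt is cooperative iff both hunters are in range
at the trigger step.  Captured prey respawn immediately at a random
clear position of the same kind, so prey counts are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .controller import ControllerArchitecture, decode_genome
from .core import (KIND_HARE, KIND_HUNTER, KIND_NONE, KIND_STAG, HuntEvent,
                   RewardTable, SimConfig, derive_seed)

__all__ = ["WorldState", "EpisodeResult", "place_agents", "step_hunter",
           "resolve_collisions", "cast_ray", "update_captures", "run_episode"]

_PLACEMENT_TRIES = 10000


@dataclass
class WorldState:
    """Array-backed world: poses, kinds, capture counters, step index.

    Rows 0 and 1 of ``positions`` are the hunters; the remaining rows are
    prey.  ``counters[p]`` tracks prey row ``p + 2``.
    """

    config: SimConfig
    positions: np.ndarray  # (n_agents, 2) float64
    headings: np.ndarray   # (2,) float64
    kinds: np.ndarray      # (n_agents,) int64
    counters: np.ndarray   # (n_prey,) int64
    step: int = 0

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]

    @property
    def n_prey(self) -> int:
        return self.n_agents - 2

    @property
    def radius(self) -> float:
        return self.config.body.radius

    def prey_counts(self) -> tuple[int, int]:
        """(n_hares, n_stags) currently in the world."""
        kinds = self.kinds[2:]
        return int(np.sum(kinds == KIND_HARE)), int(np.sum(kinds == KIND_STAG))

    def copy(self) -> "WorldState":
        return WorldState(self.config, self.positions.copy(),
                          self.headings.copy(), self.kinds.copy(),
                          self.counters.copy(), self.step)


@dataclass
class EpisodeResult:
    """Outcome of one episode: payoffs, hunt events, category counts."""

    payoffs: np.ndarray                 # (2,) food-units
    events: list[HuntEvent]
    n_hares: int
    n_coop_stags: int
    n_solo_stags: int
    trajectories: np.ndarray | None = field(default=None, repr=False)

    @property
    def counts(self) -> tuple[int, int, int]:
        return self.n_hares, self.n_coop_stags, self.n_solo_stags


def place_agents(config: SimConfig, rng: np.random.Generator) -> WorldState:
    """Place 2 hunters and the configured prey uniformly without overlap.

    Positions are rejection-sampled uniformly over the arena interior
    (centres at least one radius from every wall) until no two disks
    overlap; hunter headings are uniform in [0, 2*pi).
    """
    arena, body, evo = config.arena, config.body, config.evo
    n_agents = 2 + evo.n_prey
    r = body.radius
    if arena.width < 2 * r or arena.height < 2 * r:
        raise ValueError("arena smaller than one agent body")
    positions = np.empty((n_agents, 2))
    min_sep2 = (2 * r) ** 2
    for i in range(n_agents):
        for attempt in range(_PLACEMENT_TRIES):
            x = r + rng.random() * (arena.width - 2 * r)
            y = r + rng.random() * (arena.height - 2 * r)
            d2 = ((positions[:i, 0] - x) ** 2 + (positions[:i, 1] - y) ** 2)
            if i == 0 or float(d2.min()) >= min_sep2:
                positions[i] = (x, y)
                break
        else:
            raise RuntimeError(
                f"could not place agent {i} after {_PLACEMENT_TRIES} tries: "
                "arena too crowded")
    headings = rng.random(2) * 2 * np.pi
    kinds = np.empty(n_agents, dtype=np.int64)
    kinds[:2] = KIND_HUNTER
    kinds[2:2 + evo.n_hares] = KIND_HARE
    kinds[2 + evo.n_hares:] = KIND_STAG
    counters = np.zeros(evo.n_prey, dtype=np.int64)
    return WorldState(config, positions, headings, kinds, counters)


def step_hunter(world: WorldState, hunter_id: int,
                wheel_speeds: tuple[float, float]) -> None:
    """Advance one hunter by differential-drive kinematics, in place.

    heading' = heading + (v_right - v_left) / wheel_base with wheel_base
    equal to the body diameter; the centre then advances by the mean
    wheel speed along the new heading.  Collisions are resolved
    immediately (walls clamped, disks pushed to contact).
    """
    v_left, v_right = wheel_speeds
    _kernels.move_and_resolve_kernel(
        hunter_id, world.positions, world.headings, float(v_left),
        float(v_right), world.radius, world.config.arena.width,
        world.config.arena.height)


def resolve_collisions(world: WorldState, moving_id: int) -> None:
    """Push the moving agent out of walls and other disks, in place."""
    _kernels.move_and_resolve_kernel(
        moving_id, world.positions, world.headings, 0.0, 0.0, world.radius,
        world.config.arena.width, world.config.arena.height)


def cast_ray(world: WorldState, origin: tuple[float, float], angle: float,
             exclude_id: int = -1) -> tuple[int, float]:
    """First agent disk hit along the ray from ``origin`` at ``angle``.

    Returns ``(kind, distance)``; if no agent is intersected the ray
    terminates on the wall and kind is ``KIND_NONE``.  ``exclude_id``
    removes the casting agent's own body.
    """
    dx, dy = np.cos(angle), np.sin(angle)
    kind, t = _kernels.nearest_agent_hit(
        float(origin[0]), float(origin[1]), float(dx), float(dy),
        world.positions, world.kinds, int(exclude_id), world.radius)
    if kind == KIND_NONE:
        t = _kernels.ray_wall_dist(float(origin[0]), float(origin[1]),
                                   float(dx), float(dy),
                                   world.config.arena.width,
                                   world.config.arena.height)
    return int(kind), float(t)


def update_captures(world: WorldState, rewards: RewardTable,
                    rng: np.random.Generator | None = None,
                    payoffs: np.ndarray | None = None) -> list[HuntEvent]:
    """Advance all capture counters one step; capture and respawn, in place.

    Counters advance while at least one hunter is within
    ``catch_distance`` and (unless cumulative capture is configured)
    reset on any step with no hunter in range.  Returns the events
    triggered this step; ``payoffs`` (length 2) accumulates rewards when
    given.  ``rng`` reseeds the respawn sampler for reproducibility.
    """
    if rng is not None:
        _kernels.seed_kernel_rng(derive_seed(rng))
    if payoffs is None:
        payoffs = np.zeros(2)
    evo = world.config.evo
    n_prey = world.n_prey
    cap = max(1, n_prey)
    ev_time = np.empty(cap, dtype=np.int64)
    ev_kind = np.empty(cap, dtype=np.int64)
    ev_coop = np.empty(cap, dtype=np.int64)
    ev_p0 = np.empty(cap, dtype=np.int64)
    ev_p1 = np.empty(cap, dtype=np.int64)
    ev_reward = np.empty(cap)
    n = _kernels.capture_step_kernel(
        world.positions, world.kinds, world.counters, world.step,
        evo.catch_distance, evo.capture_steps, evo.cumulative_capture,
        rewards.as_array(), world.radius, world.config.arena.width,
        world.config.arena.height, payoffs,
        ev_time, ev_kind, ev_coop, ev_p0, ev_p1, ev_reward, 0)
    world.step += 1
    return _events_from_arrays(ev_time, ev_kind, ev_coop, ev_p0, ev_p1,
                               ev_reward, n)


def _events_from_arrays(ev_time, ev_kind, ev_coop, ev_p0, ev_p1, ev_reward,
                        n: int) -> list[HuntEvent]:
    events = []
    for k in range(n):
        participants = tuple(h for h, flag in ((0, ev_p0[k]), (1, ev_p1[k]))
                             if flag)
        events.append(HuntEvent(time=int(ev_time[k]), prey_kind=int(ev_kind[k]),
                                cooperative=bool(ev_coop[k]),
                                participants=participants,
                                reward_per_hunter=float(ev_reward[k])))
    return events


def run_episode(genome_a: np.ndarray, genome_b: np.ndarray, config: SimConfig,
                rng: np.random.Generator | int,
                record_trajectories: bool = False) -> EpisodeResult:
    """Simulate one full episode of two hunters in a fresh random world.

    Each step runs, for each hunter in id order: perceive, control, move,
    resolve collisions; then the capture counters update once.  The
    result is deterministic given the genomes, config and rng state.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    arch = ControllerArchitecture.from_config(config.body, config.controller)
    w1a, w2a = decode_genome(genome_a, arch)
    w1b, w2b = decode_genome(genome_b, arch)
    w1a = np.ascontiguousarray(w1a.T)  # kernel wants (hidden, inputs)
    w1b = np.ascontiguousarray(w1b.T)
    world = place_agents(config, rng)
    respawn_seed = derive_seed(rng)
    evo, body, arena = config.evo, config.body, config.arena
    traj = (np.empty((evo.episode_steps, 2, 3))
            if record_trajectories else np.empty((1, 2, 3)))
    out = _kernels.run_episode_kernel(
        world.positions, world.headings, world.kinds, world.counters,
        w1a, w2a, w1b, w2b,
        body.radius, body.n_proximity, body.proximity_range,
        body.n_camera_rays, np.deg2rad(body.camera_fov),
        arena.width, arena.height, config.controller.v_max,
        evo.catch_distance, evo.capture_steps, evo.cumulative_capture,
        evo.episode_steps, config.rewards.as_array(), respawn_seed,
        record_trajectories, traj)
    payoffs, ev_time, ev_kind, ev_coop, ev_p0, ev_p1, ev_reward, n = out
    events = _events_from_arrays(ev_time, ev_kind, ev_coop, ev_p0, ev_p1,
                                 ev_reward, n)
    n_hares = sum(1 for e in events if e.prey_kind == KIND_HARE)
    n_coop = sum(1 for e in events if e.prey_kind == KIND_STAG and e.cooperative)
    n_solo = sum(1 for e in events if e.prey_kind == KIND_STAG and not e.cooperative)
    return EpisodeResult(payoffs=payoffs, events=events, n_hares=n_hares,
                         n_coop_stags=n_coop, n_solo_stags=n_solo,
                         trajectories=traj if record_trajectories else None)
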