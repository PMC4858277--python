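"""Shared test utilities: stepwise episode driver and independent oracles."""

from __future__ import annotations

import numpy as np

import staghunt as sh
from staghunt import _kernels, perception
from staghunt.controller import ControllerArchitecture, decode_genome, forward
from staghunt.core import KIND_NONE, derive_seed
from staghunt.engine import (WorldState, place_agents, step_hunter,
                             update_captures)


def assert_world_invariants(world: WorldState, n_hares: int, n_stags: int,
                            tol: float = 1e-9) -> None:
    """Prey conservation, no interpenetration, walls respected."""
    got_h, got_s = world.prey_counts()
    assert (got_h, got_s) == (n_hares, n_stags)
    pos = world.positions
    r = world.radius
    arena = world.config.arena
    assert np.all(pos[:, 0] >= r - tol) and np.all(pos[:, 0] <= arena.width - r + tol)
    assert np.all(pos[:, 1] >= r - tol) and np.all(pos[:, 1] <= arena.height - r + tol)
    # Only hunters move, so only hunter pairs can interpenetrate; check all.
    for i in range(2):
        d = np.hypot(pos[:, 0] - pos[i, 0], pos[:, 1] - pos[i, 1])
        d[i] = np.inf
        assert d.min() >= 2 * r - tol, f"interpenetration at step {world.step}"


def run_episode_stepwise(genome_a, genome_b, config, rng,
                         n_steps=None, check_every=1):
    """Drive an episode through the public per-step operations.

    Mirrors the compiled episode loop exactly (same kernels, same RNG
    usage) so its outcome can be compared with
    :func:`staghunt.run_episode`; asserts world invariants as it goes.
    Returns (payoffs, events, world).
    """
    arch = ControllerArchitecture.from_config(config.body, config.controller)
    wa = decode_genome(genome_a, arch)
    wb = decode_genome(genome_b, arch)
    world = place_agents(config, rng)
    _kernels.seed_kernel_rng(derive_seed(rng))
    evo = config.evo
    if n_steps is None:
        n_steps = evo.episode_steps
    payoffs = np.zeros(2)
    events = []
    v_max = config.controller.v_max
    for step in range(n_steps):
        for i, w in ((0, wa), (1, wb)):
            x = perception.build_input_vector(world, i)
            o1, o2 = forward(w, x)
            vl = (2.0 * o1 - 1.0) * v_max
            vr = (2.0 * o2 - 1.0) * v_max
            step_hunter(world, i, (vl, vr))
        events.extend(update_captures(world, config.rewards, payoffs=payoffs))
        if step % check_every == 0:
            assert_world_invariants(world, evo.n_hares, evo.n_stags)
    return payoffs, events, world


def oracle_cast_ray(world: WorldState, origin, angle, exclude_id=-1):
    """Exhaustive all-disks ray intersection, written independently.

    Solves the quadratic |o + t d - c|^2 = r^2 per disk via np.roots and
    takes the smallest non-negative real root over all disks; falls back
    to the wall otherwise.
    """
    d = np.array([np.cos(angle), np.sin(angle)])
    o = np.asarray(origin, dtype=float)
    best = (KIND_NONE, np.inf)
    for j in range(world.n_agents):
        if j == exclude_id:
            continue
        f = o - world.positions[j]
        roots = np.roots([1.0, 2.0 * f @ d, f @ f - world.radius**2])
        ts = [float(t.real) for t in roots
              if abs(t.imag) < 1e-12 and t.real >= 0.0]
        if ts and min(ts) < best[1]:
            best = (int(world.kinds[j]), min(ts))
    if best[0] == KIND_NONE:
        arena = world.config.arena
        ts = []
        for axis, bound in ((0, 0.0), (0, arena.width), (1, 0.0), (1, arena.height)):
            if d[axis] != 0.0:
                t = (bound - o[axis]) / d[axis]
                if t >= 0.0:
                    ts.append(t)
        best = (KIND_NONE, min(ts))
    return best


def random_world(config, rng, n_hares=None, n_stags=None) -> WorldState:
    cfg = config
    if n_hares is not None or n_stags is not None:
        cfg = config.replace(evo=dict(
            n_hares=config.evo.n_hares if n_hares is None else n_hares,
            n_stags=config.evo.n_stags if n_stags is None else n_stags))
    world = place_agents(cfg, rng)
    world.headings[:] = rng.random(2) * 2 * np.pi
    return world


def exact_mwu_p_by_enumeration(a, b) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration (no ties).

    Enumerates every assignment of pooled ranks to sample a; by the
    symmetry of the null distribution of U about n_a*n_b/2, the
    two-sided p is P(U <= u_low) + P(U >= n_a*n_b - u_low).
    """
    from itertools import combinations

    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    assert np.unique(pooled).size == pooled.size, "oracle requires no ties"
    ranks = rankdata(pooled)
    n_a, n_b = len(a), len(b)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    u_low = min(u_obs, n_a * n_b - u_obs)
    us = []
    for combo in combinations(range(1, n_a + n_b + 1), n_a):
        us.append(sum(combo) - n_a * (n_a + 1) / 2)
    us = np.array(us)
    p = float(np.mean(us <= u_low) + np.mean(us >= n_a * n_b - u_low))
    return min(1.0, p)
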