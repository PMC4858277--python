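"""Numba-compiled inner loops shared by the engine and perception modules.

Everything here operates on plain arrays so the same code path serves
both the per-step Python-level operations (used by unit tests and
fixtures) and the full-episode runner used during evolution.

Conventions
-----------
* positions: float64 (n_agents, 2); rows 0 and 1 are the hunters.
* kinds: int64 (n_agents,); 0 = hunter, 1 = hare, 2 = stag.
* All agents are disks of one common radius.
* Respawn randomness uses numba's internal np.random state, seeded once
  per episode (or explicitly via :func:`seed_kernel_rng`).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

KIND_NONE = -1
KIND_HUNTER = 0
KIND_HARE = 1
KIND_STAG = 2

#: Upper bound on wall/ray distances, stands in for "no hit".
NO_HIT = 1.0e18


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def ray_circle_dist(ox, oy, dx, dy, cx, cy, r):
    """Distance along unit ray (ox,oy)+t(dx,dy) to the disk boundary, or NO_HIT.

    Returns the smallest non-negative t; an origin inside the disk hits
    the far boundary.
    """
    fx = cx - ox
    fy = cy - oy
    b = fx * dx + fy * dy
    disc = r * r - (fx * fx + fy * fy - b * b)
    if disc < 0.0:
        return NO_HIT
    s = math.sqrt(disc)
    t = b - s
    if t >= 0.0:
        return t
    t = b + s
    if t >= 0.0:
        return t
    return NO_HIT


@njit(cache=True, inline="always")
def ray_wall_dist(ox, oy, dx, dy, width, height):
    """Distance along unit ray to the nearest arena wall."""
    t = NO_HIT
    if dx > 0.0:
        t = min(t, (width - ox) / dx)
    elif dx < 0.0:
        t = min(t, -ox / dx)
    if dy > 0.0:
        t = min(t, (height - oy) / dy)
    elif dy < 0.0:
        t = min(t, -oy / dy)
    if t < 0.0:
        t = 0.0
    return t


@njit(cache=True)
def nearest_agent_hit(ox, oy, dx, dy, positions, kinds, exclude, radius):
    """First agent disk intersected by the ray; (kind, t) or (KIND_NONE, NO_HIT)."""
    best_t = NO_HIT
    best_k = KIND_NONE
    for j in range(positions.shape[0]):
        if j == exclude:
            continue
        t = ray_circle_dist(ox, oy, dx, dy, positions[j, 0], positions[j, 1], radius)
        if t < best_t:
            best_t = t
            best_k = kinds[j]
    return best_k, best_t


@njit(cache=True)
def proximity_activation_kernel(i, sensor_index, positions, kinds, heading,
                                radius, n_proximity, prox_range, width, height):
    """Activation of one proximity sensor: 1 at contact, 0 beyond range.

    d is measured from the body surface along the sensor ray to the
    nearest obstacle surface (wall or agent disk); activation is the
    linear ramp max(0, 1 - d / prox_range).
    """
    ang = heading + sensor_index * (2.0 * math.pi / n_proximity)
    dx = math.cos(ang)
    dy = math.sin(ang)
    ox = positions[i, 0]
    oy = positions[i, 1]
    _, t_agent = nearest_agent_hit(ox, oy, dx, dy, positions, kinds, i, radius)
    t_wall = ray_wall_dist(ox, oy, dx, dy, width, height)
    t = t_agent if t_agent < t_wall else t_wall
    d = t - radius
    if d < 0.0:
        d = 0.0
    act = 1.0 - d / prox_range
    if act < 0.0:
        act = 0.0
    return act


@njit(cache=True, inline="always")
def camera_ray_angle(heading, ray_index, n_rays, fov_rad):
    """Ray angles centred on the heading, evenly spaced at bin centres."""
    return heading - fov_rad / 2.0 + (ray_index + 0.5) * fov_rad / n_rays


@njit(cache=True)
def camera_ray_kernel(i, ray_index, positions, kinds, heading, radius,
                      n_rays, fov_rad, diag, width, height, out):
    """Fill out[0:4] with (type_bit_1, type_bit_2, proximity, presence).

    Type code: none=(0,0), hunter=(0,1), hare=(1,0), stag=(1,1).
    Proximity is max(0, 1 - d/diag) where d runs from the body surface to
    whatever terminated the ray (agent disk, else wall).
    """
    ang = camera_ray_angle(heading, ray_index, n_rays, fov_rad)
    dx = math.cos(ang)
    dy = math.sin(ang)
    ox = positions[i, 0]
    oy = positions[i, 1]
    kind, t = nearest_agent_hit(ox, oy, dx, dy, positions, kinds, i, radius)
    if kind == KIND_NONE:
        t = ray_wall_dist(ox, oy, dx, dy, width, height)
        out[0] = 0.0
        out[1] = 0.0
        out[3] = 0.0
    else:
        if kind == KIND_HUNTER:
            out[0] = 0.0
            out[1] = 1.0
        elif kind == KIND_HARE:
            out[0] = 1.0
            out[1] = 0.0
        else:
            out[0] = 1.0
            out[1] = 1.0
        out[3] = 1.0
    d = t - radius
    if d < 0.0:
        d = 0.0
    prox = 1.0 - d / diag
    if prox < 0.0:
        prox = 0.0
    out[2] = prox
    return kind


@njit(cache=True)
def build_input_kernel(i, positions, kinds, heading, radius, n_proximity,
                       prox_range, n_rays, fov_rad, diag, width, height, out,
                       cam_t, cam_kind, pdx, pdy, cdx, cdy):
    """Fill the 61-value input: 12 proximity, 12 x 4 camera, bias = 1.

    Equivalent to running :func:`proximity_activation_kernel` and
    :func:`camera_ray_kernel` per ray (a standing test asserts so), but
    agents that provably cannot intersect a ray are culled up front: the
    per-pair intersection math is unchanged for the pairs actually
    tested.
    """
    ox = positions[i, 0]
    oy = positions[i, 1]
    n_agents = positions.shape[0]
    two_pi = 2.0 * math.pi

    # Ray direction tables by rotation recurrence (one trig pair per fan).
    c = math.cos(heading)
    s = math.sin(heading)
    cd = math.cos(two_pi / n_proximity)
    sd = math.sin(two_pi / n_proximity)
    for k in range(n_proximity):
        pdx[k] = c
        pdy[k] = s
        c, s = c * cd - s * sd, s * cd + c * sd
    spacing = fov_rad / n_rays
    a0 = heading - fov_rad / 2.0 + 0.5 * spacing
    c = math.cos(a0)
    s = math.sin(a0)
    cd = math.cos(spacing)
    sd = math.sin(spacing)
    for k in range(n_rays):
        cdx[k] = c
        cdy[k] = s
        c, s = c * cd - s * sd, s * cd + c * sd

    # --- proximity ring -------------------------------------------------
    # Wall contribution: zero for every ray if all walls are out of range.
    reach = prox_range + radius
    walls_near = (ox < reach or oy < reach or
                  width - ox < reach or height - oy < reach)
    for k in range(n_proximity):
        t = (ray_wall_dist(ox, oy, pdx[k], pdy[k], width, height)
             if walls_near else NO_HIT)
        out[k] = t  # temporarily store nearest t per ray
    # An agent at centre distance d is only reachable along some ray if
    # d - r <= radius + prox_range (surface distance within range).
    max_d = prox_range + 2.0 * radius
    for j in range(n_agents):
        if j == i:
            continue
        fx = positions[j, 0] - ox
        fy = positions[j, 1] - oy
        if fx * fx + fy * fy > max_d * max_d:
            continue
        for k in range(n_proximity):
            t = ray_circle_dist(ox, oy, pdx[k], pdy[k],
                                positions[j, 0], positions[j, 1], radius)
            if t < out[k]:
                out[k] = t
    for k in range(n_proximity):
        d = out[k] - radius
        if d < 0.0:
            d = 0.0
        act = 1.0 - d / prox_range
        out[k] = act if act > 0.0 else 0.0

    # --- camera cone ----------------------------------------------------
    base = n_proximity
    for j in range(n_rays):
        cam_t[j] = NO_HIT
        cam_kind[j] = KIND_NONE
    for j in range(n_agents):
        if j == i:
            continue
        fx = positions[j, 0] - ox
        fy = positions[j, 1] - oy
        d = math.sqrt(fx * fx + fy * fy)
        # Angular window of the disk about the hunter, relative to heading.
        if d <= radius:
            rel_lo = -fov_rad / 2.0
            rel_hi = fov_rad / 2.0
        else:
            phi = math.atan2(fy, fx) - heading
            phi = (phi + math.pi) % two_pi - math.pi
            alpha = math.asin(min(1.0, radius / d))
            rel_lo = phi - alpha
            rel_hi = phi + alpha
        # Candidate ray indices: angles -fov/2 + (k + 0.5) * spacing.
        k_lo = int(math.ceil((rel_lo + fov_rad / 2.0) / spacing - 0.5))
        k_hi = int(math.floor((rel_hi + fov_rad / 2.0) / spacing - 0.5))
        if k_lo < 0:
            k_lo = 0
        if k_hi > n_rays - 1:
            k_hi = n_rays - 1
        for k in range(k_lo, k_hi + 1):
            t = ray_circle_dist(ox, oy, cdx[k], cdy[k],
                                positions[j, 0], positions[j, 1], radius)
            if t < cam_t[k]:
                cam_t[k] = t
                cam_kind[k] = kinds[j]
    for k in range(n_rays):
        kind = cam_kind[k]
        t = cam_t[k]
        if kind == KIND_NONE:
            t = ray_wall_dist(ox, oy, cdx[k], cdy[k], width, height)
        d = t - radius
        if d < 0.0:
            d = 0.0
        prox = 1.0 - d / diag
        if prox < 0.0:
            prox = 0.0
        q = base + 4 * k
        if kind == KIND_NONE:
            out[q] = 0.0
            out[q + 1] = 0.0
            out[q + 3] = 0.0
        elif kind == KIND_HUNTER:
            out[q] = 0.0
            out[q + 1] = 1.0
            out[q + 3] = 1.0
        elif kind == KIND_HARE:
            out[q] = 1.0
            out[q + 1] = 0.0
            out[q + 3] = 1.0
        else:
            out[q] = 1.0
            out[q + 1] = 1.0
            out[q + 3] = 1.0
        out[q + 2] = prox
    out[base + 4 * n_rays] = 1.0


@njit(cache=True, inline="always")
def sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


@njit(cache=True, fastmath=True)
def mlp_forward_kernel(x, w1t, w2, hidden, out):
    """Single-hidden-layer sigmoid MLP, written into ``out``.

    w1t: (n_hidden, n_inputs), the transposed input-to-hidden weights so
    the inner dot product runs over contiguous memory; w2:
    (n_hidden + 1, n_outputs) with the last row the hidden-layer bias;
    ``hidden`` is scratch of length n_hidden.
    """
    n_hid = w1t.shape[0]
    n_in = w1t.shape[1]
    for j in range(n_hid):
        s = 0.0
        for k in range(n_in):
            s += x[k] * w1t[j, k]
        hidden[j] = sigmoid(s)
    for m in range(w2.shape[1]):
        s = w2[n_hid, m]
        for j in range(n_hid):
            s += hidden[j] * w2[j, m]
        out[m] = sigmoid(s)


@njit(cache=True)
def move_and_resolve_kernel(i, positions, headings, v_left, v_right,
                            radius, width, height):
    """Differential-drive step for hunter i, then collision resolution.

    heading' = heading + (v_r - v_l)/wheel_base (wheel_base = diameter);
    the centre advances by the mean wheel speed along the new heading.
    Resolution pushes the mover out of walls (axis clamp) and out of any
    other disk (along the centre-to-centre axis to exact contact),
    iterating until stable; only the moving agent is displaced.
    """
    wheel_base = 2.0 * radius
    h = headings[i] + (v_right - v_left) / wheel_base
    h = h % (2.0 * math.pi)
    headings[i] = h
    v = 0.5 * (v_left + v_right)
    positions[i, 0] += v * math.cos(h)
    positions[i, 1] += v * math.sin(h)

    min_sep = 2.0 * radius
    for _ in range(8):
        moved = False
        x = positions[i, 0]
        y = positions[i, 1]
        if x < radius:
            x = radius
            moved = True
        elif x > width - radius:
            x = width - radius
            moved = True
        if y < radius:
            y = radius
            moved = True
        elif y > height - radius:
            y = height - radius
            moved = True
        positions[i, 0] = x
        positions[i, 1] = y
        for j in range(positions.shape[0]):
            if j == i:
                continue
            ddx = positions[i, 0] - positions[j, 0]
            ddy = positions[i, 1] - positions[j, 1]
            d = math.sqrt(ddx * ddx + ddy * ddy)
            if d < min_sep - 1e-12:
                if d < 1e-9:
                    # Coincident centres: push along +x by convention.
                    positions[i, 0] = positions[j, 0] + min_sep
                else:
                    positions[i, 0] = positions[j, 0] + ddx / d * min_sep
                    positions[i, 1] = positions[j, 1] + ddy / d * min_sep
                moved = True
        if not moved:
            break


@njit(cache=True)
def respawn_position_kernel(positions, skip, radius, width, height):
    """Rejection-sample a position clear of walls and all disks but `skip`.

    Returns (x, y, ok); after 10000 rejections ok is False and the last
    sample is returned unplaced-checked.
    """
    min_sep = 2.0 * radius
    x = width / 2.0
    y = height / 2.0
    for _ in range(10000):
        x = radius + np.random.random() * (width - 2.0 * radius)
        y = radius + np.random.random() * (height - 2.0 * radius)
        ok = True
        for j in range(positions.shape[0]):
            if j == skip:
                continue
            ddx = x - positions[j, 0]
            ddy = y - positions[j, 1]
            if ddx * ddx + ddy * ddy < min_sep * min_sep:
                ok = False
                break
        if ok:
            return x, y, True
    return x, y, False


@njit(cache=True)
def capture_step_kernel(positions, kinds, counters, step, catch_distance,
                        capture_steps, cumulative, rewards, radius,
                        width, height, payoffs,
                        ev_time, ev_kind, ev_coop, ev_p0, ev_p1, ev_reward,
                        n_events):
    """One capture-counter update after all movement in a step.

    Each prey's counter advances while at least one hunter is within
    catch_distance (centre-to-centre); without the cumulative flag it
    resets to zero on any step with no hunter in range.  On reaching
    capture_steps the prey is captured — cooperatively iff both hunters
    are in range at that step — every in-range hunter receives the full
    table reward, and the prey respawns at a random clear position with a
    zeroed counter.  Returns the updated event count.
    """
    catch2 = catch_distance * catch_distance
    for p in range(2, positions.shape[0]):
        in0 = ((positions[p, 0] - positions[0, 0]) ** 2 +
               (positions[p, 1] - positions[0, 1]) ** 2) <= catch2
        in1 = ((positions[p, 0] - positions[1, 0]) ** 2 +
               (positions[p, 1] - positions[1, 1]) ** 2) <= catch2
        if in0 or in1:
            counters[p - 2] += 1
        elif not cumulative:
            counters[p - 2] = 0
        if counters[p - 2] >= capture_steps:
            coop = in0 and in1
            r = rewards[kinds[p] - 1, 1 if coop else 0]
            if in0:
                payoffs[0] += r
            if in1:
                payoffs[1] += r
            if n_events < ev_time.shape[0]:
                ev_time[n_events] = step
                ev_kind[n_events] = kinds[p]
                ev_coop[n_events] = 1 if coop else 0
                ev_p0[n_events] = 1 if in0 else 0
                ev_p1[n_events] = 1 if in1 else 0
                ev_reward[n_events] = r
                n_events += 1
            x, y, _ = respawn_position_kernel(positions, p, radius, width, height)
            positions[p, 0] = x
            positions[p, 1] = y
            counters[p - 2] = 0
    return n_events


@njit(cache=True)
def run_episode_kernel(positions, headings, kinds, counters,
                       w1a, w2a, w1b, w2b,
                       radius, n_proximity, prox_range, n_rays, fov_rad,
                       width, height, v_max,
                       catch_distance, capture_steps, cumulative,
                       episode_steps, rewards, respawn_seed,
                       record_traj, traj):
    """Simulate one full episode in place; returns (payoffs, events..., n_events).

    Per step, each hunter in id order perceives the current world,
    computes wheel speeds, moves, and has its collisions resolved; then
    capture counters update once.  All arrays are mutated in place.
    """
    np.random.seed(respawn_seed)
    diag = math.sqrt(width * width + height * height)
    n_inputs = n_proximity + 4 * n_rays + 1
    x = np.empty(n_inputs)
    cam_t = np.empty(n_rays)
    cam_kind = np.empty(n_rays, dtype=np.int64)
    pdx = np.empty(n_proximity)
    pdy = np.empty(n_proximity)
    cdx = np.empty(n_rays)
    cdy = np.empty(n_rays)
    hidden_a = np.empty(w1a.shape[0])  # w1a/w1b are transposed: (hid, in)
    hidden_b = np.empty(w1b.shape[0])
    o = np.empty(2)
    payoffs = np.zeros(2)
    n_prey = positions.shape[0] - 2
    max_events = n_prey * (episode_steps // max(capture_steps, 1) + 1) + 1
    ev_time = np.empty(max_events, dtype=np.int64)
    ev_kind = np.empty(max_events, dtype=np.int64)
    ev_coop = np.empty(max_events, dtype=np.int64)
    ev_p0 = np.empty(max_events, dtype=np.int64)
    ev_p1 = np.empty(max_events, dtype=np.int64)
    ev_reward = np.empty(max_events)
    n_events = 0

    for step in range(episode_steps):
        for i in range(2):
            build_input_kernel(i, positions, kinds, headings[i], radius,
                               n_proximity, prox_range, n_rays, fov_rad,
                               diag, width, height, x, cam_t, cam_kind,
                               pdx, pdy, cdx, cdy)
            if i == 0:
                mlp_forward_kernel(x, w1a, w2a, hidden_a, o)
            else:
                mlp_forward_kernel(x, w1b, w2b, hidden_b, o)
            v_left = (2.0 * o[0] - 1.0) * v_max
            v_right = (2.0 * o[1] - 1.0) * v_max
            move_and_resolve_kernel(i, positions, headings, v_left, v_right,
                                    radius, width, height)
        n_events = capture_step_kernel(
            positions, kinds, counters, step, catch_distance, capture_steps,
            cumulative, rewards, radius, width, height, payoffs,
            ev_time, ev_kind, ev_coop, ev_p0, ev_p1, ev_reward, n_events)
        if record_traj:
            for i in range(2):
                traj[step, i, 0] = positions[i, 0]
                traj[step, i, 1] = positions[i, 1]
                traj[step, i, 2] = headings[i]
    return payoffs, ev_time, ev_kind, ev_coop, ev_p0, ev_p1, ev_reward, n_events
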