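"""Hunter sensors: proximity ring and typed camera cone.

A hunter's 61-value input vector concatenates 12 proximity activations
(obstacle nearness over 360 degrees, range about two body diameters),
12 camera rays of 4 values each (two type bits, a proximity value, and a
presence flag), and a constant bias of 1.  Proximity sensors respond to
walls and agent bodies alike; only the camera identifies agent types.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .core import KIND_HARE, KIND_HUNTER, KIND_NONE, KIND_STAG
from .engine import WorldState

__all__ = ["proximity_activation", "camera_ray_values", "build_input_vector",
           "camera_ray_angle", "input_length"]

#: Two-bit type code per camera ray: (bit_1, bit_2).
TYPE_BITS = {KIND_NONE: (0.0, 0.0), KIND_HUNTER: (0.0, 1.0),
             KIND_HARE: (1.0, 0.0), KIND_STAG: (1.0, 1.0)}


def input_length(world: WorldState) -> int:
    body = world.config.body
    return body.n_proximity + 4 * body.n_camera_rays + 1


def proximity_activation(world: WorldState, hunter_id: int,
                         sensor_index: int) -> float:
    """Activation of one proximity sensor in [0, 1].

    Sensor k points at heading + k * (360 / n_proximity) degrees.  With d
    the distance from the body surface along the sensor ray to the
    nearest obstacle surface (wall or agent disk), the activation is
    max(0, 1 - d / proximity_range): 1 at contact, 0 beyond range.
    """
    body = world.config.body
    if not 0 <= sensor_index < body.n_proximity:
        raise IndexError(f"sensor_index {sensor_index} out of range")
    return float(_kernels.proximity_activation_kernel(
        hunter_id, sensor_index, world.positions, world.kinds,
        world.headings[hunter_id], body.radius, body.n_proximity,
        body.proximity_range, world.config.arena.width,
        world.config.arena.height))


def camera_ray_angle(world: WorldState, hunter_id: int, ray_index: int) -> float:
    """Absolute angle of one camera ray (bin-centre spacing across the fov)."""
    body = world.config.body
    return float(_kernels.camera_ray_angle(
        world.headings[hunter_id], ray_index, body.n_camera_rays,
        np.deg2rad(body.camera_fov)))


def camera_ray_values(world: WorldState, hunter_id: int, ray_index: int
                      ) -> tuple[float, float, float, float]:
    """(type_bit_1, type_bit_2, proximity, presence) for one camera ray.

    Rays are spread evenly across the field of view centred on the
    heading.  The type code is none=(0,0), hunter=(0,1), hare=(1,0),
    stag=(1,1).  Rays have unbounded range, so proximity is normalised by
    the arena diagonal: max(0, 1 - d / diagonal), with d measured from
    the body surface to whatever terminated the ray (the first agent
    disk, else the wall).  presence is 1 iff an agent was hit, so "no
    target" is distinguishable from "far target".
    """
    body = world.config.body
    if not 0 <= ray_index < body.n_camera_rays:
        raise IndexError(f"ray_index {ray_index} out of range")
    out = np.empty(4)
    _kernels.camera_ray_kernel(
        hunter_id, ray_index, world.positions, world.kinds,
        world.headings[hunter_id], body.radius, body.n_camera_rays,
        np.deg2rad(body.camera_fov), world.config.arena.diagonal,
        world.config.arena.width, world.config.arena.height, out)
    return tuple(float(v) for v in out)


def build_input_vector(world: WorldState, hunter_id: int) -> np.ndarray:
    """Full sensory input: [proximity | per-ray quadruples | bias = 1]."""
    body = world.config.body
    out = np.empty(input_length(world))
    cam_t = np.empty(body.n_camera_rays)
    cam_kind = np.empty(body.n_camera_rays, dtype=np.int64)
    pdx = np.empty(body.n_proximity)
    pdy = np.empty(body.n_proximity)
    cdx = np.empty(body.n_camera_rays)
    cdy = np.empty(body.n_camera_rays)
    _kernels.build_input_kernel(
        hunter_id, world.positions, world.kinds, world.headings[hunter_id],
        body.radius, body.n_proximity, body.proximity_range,
        body.n_camera_rays, np.deg2rad(body.camera_fov),
        world.config.arena.diagonal, world.config.arena.width,
        world.config.arena.height, out, cam_t, cam_kind, pdx, pdy, cdx, cdy)
    return out
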