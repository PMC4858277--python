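"""Deterministic hand-placed arena scenarios for tests and demos.

Each scenario builds a :class:`~staghunt.engine.WorldState` with agents
at exact positions, so perception, capture and collision code can be
checked against closed-form geometry.
"""

from __future__ import annotations

import numpy as np

from .core import KIND_HARE, KIND_HUNTER, KIND_STAG, SimConfig
from .engine import WorldState

__all__ = ["build_fixture", "FIXTURES"]


def _world(cfg: SimConfig, hunters, prey) -> WorldState:
    """hunters: [(x, y, heading)]; prey: [(x, y, kind)]."""
    n = len(hunters) + len(prey)
    positions = np.empty((n, 2))
    headings = np.zeros(2)
    kinds = np.empty(n, dtype=np.int64)
    for i, (x, y, h) in enumerate(hunters):
        positions[i] = (x, y)
        headings[i] = h
        kinds[i] = KIND_HUNTER
    for p, (x, y, k) in enumerate(prey):
        positions[len(hunters) + p] = (x, y)
        kinds[len(hunters) + p] = k
    counters = np.zeros(len(prey), dtype=np.int64)
    n_hares = sum(1 for *_, k in prey if k == KIND_HARE)
    n_stags = sum(1 for *_, k in prey if k == KIND_STAG)
    cfg = cfg.replace(evo=dict(n_hares=n_hares, n_stags=n_stags))
    return WorldState(cfg, positions, headings, kinds, counters)


def _hunter_facing_stag_at_50(cfg: SimConfig) -> WorldState:
    # Hunter at arena centre, heading +x; stag centre 50 units ahead.
    cx, cy = cfg.arena.width / 2, cfg.arena.height / 2
    return _world(cfg, [(cx, cy, 0.0), (cx, cy - 200.0, 0.0)],
                  [(cx + 50.0, cy, KIND_STAG)])


def _two_hunters_flanking_prey(cfg: SimConfig) -> WorldState:
    # Both hunters 20 units from the prey centre, within catch distance.
    cx, cy = cfg.arena.width / 2, cfg.arena.height / 2
    return _world(cfg, [(cx - 20.0, cy, 0.0), (cx + 20.0, cy, np.pi)],
                  [(cx, cy, KIND_STAG)])


def _one_hunter_on_hare(cfg: SimConfig) -> WorldState:
    # Hunter 0 within catch distance of a hare; hunter 1 far away.
    cx, cy = cfg.arena.width / 2, cfg.arena.height / 2
    return _world(cfg, [(cx - 20.0, cy, 0.0), (100.0, 100.0, 0.0)],
                  [(cx, cy, KIND_HARE)])


def _corner_trap(cfg: SimConfig) -> WorldState:
    # Hunter near the origin corner, heading straight into it.
    return _world(cfg, [(20.0, 20.0, 5.0 * np.pi / 4.0),
                        (cfg.arena.width - 50.0, cfg.arena.height - 50.0, 0.0)],
                  [])


def _hunter_alone_center(cfg: SimConfig) -> WorldState:
    cx, cy = cfg.arena.width / 2, cfg.arena.height / 2
    w = _world(cfg, [(cx, cy, 0.0), (cx, cy, 0.0)], [])
    # Park the second hunter in a far corner so the first is effectively alone.
    w.positions[1] = (cfg.body.radius, cfg.body.radius)
    return w


FIXTURES = {
    "hunter-facing-stag-at-50": _hunter_facing_stag_at_50,
    "two-hunters-flanking-prey": _two_hunters_flanking_prey,
    "one-hunter-on-hare": _one_hunter_on_hare,
    "corner-trap": _corner_trap,
    "hunter-alone-center": _hunter_alone_center,
}


def build_fixture(scenario_name: str, cfg: SimConfig | None = None
                  ) -> WorldState:
    """Build a named deterministic scenario; see :data:`FIXTURES`."""
    if scenario_name not in FIXTURES:
        raise KeyError(f"unknown scenario {scenario_name!r}; "
                       f"known: {sorted(FIXTURES)}")
    return FIXTURES[scenario_name](cfg if cfg is not None else SimConfig())
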