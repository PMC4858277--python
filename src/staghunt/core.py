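"""Domain types, configuration, and the random-number contract.

The simulation models a two-player stag hunt embodied in a 2D arena:
two wheeled hunters, controlled by evolved neural networks, share an
arena with stationary prey.  Hares reward a hunter whether it is alone
or not; stags pay off only when both hunters are in catching distance
at the moment of capture.  All other modules build on the configuration
objects and the seeded-substream RNG defined here.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

__all__ = [
    "KIND_NONE",
    "KIND_HUNTER",
    "KIND_HARE",
    "KIND_STAG",
    "ArenaConfig",
    "BodySpec",
    "RewardTable",
    "ControllerConfig",
    "EvoConfig",
    "SimConfig",
    "AgentState",
    "HuntEvent",
    "make_rng",
    "load_config",
    "ConfigError",
]

# Agent kind codes shared with the numba kernels.
KIND_NONE = -1
KIND_HUNTER = 0
KIND_HARE = 1
KIND_STAG = 2

KIND_NAMES = {KIND_HUNTER: "hunter", KIND_HARE: "hare", KIND_STAG: "stag"}
NAME_KINDS = {v: k for k, v in KIND_NAMES.items()}


class ConfigError(ValueError):
    """Raised when a configuration document is invalid."""


@dataclass(frozen=True)
class ArenaConfig:
    """Axis-aligned square arena with four solid walls."""

    width: float = 800.0
    height: float = 800.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigError("arena width and height must be positive")

    @property
    def diagonal(self) -> float:
        return math.hypot(self.width, self.height)


@dataclass(frozen=True)
class BodySpec:
    """Circular agent body and its sensor layout.

    Proximity sensors are spaced evenly over 360 degrees and report the
    nearness of any obstacle (wall or agent) within roughly two body
    diameters.  The camera is a cone of rays of unbounded range centred
    on the heading; each ray reports the type and proximity of the first
    agent it intersects.
    """

    diameter: float = 14.0
    n_proximity: int = 12
    proximity_range: float = 28.0
    n_camera_rays: int = 12
    camera_fov: float = 90.0  # degrees

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ConfigError("body diameter must be positive")
        if self.n_proximity < 1 or self.n_camera_rays < 1:
            raise ConfigError("sensor counts must be >= 1")
        if not 0 < self.camera_fov <= 360:
            raise ConfigError("camera_fov must be in (0, 360] degrees")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class RewardTable:
    """Food payoffs by prey type and whether the hunt was cooperative.

    Rewards are per participating hunter; nothing is split.
    """

    hare_solo: float = 50.0
    hare_coop: float = 50.0
    stag_solo: float = 0.0
    stag_coop: float = 500.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ConfigError(f"reward {f.name} must be >= 0")

    def reward(self, kind: int, cooperative: bool) -> float:
        if kind == KIND_HARE:
            return self.hare_coop if cooperative else self.hare_solo
        if kind == KIND_STAG:
            return self.stag_coop if cooperative else self.stag_solo
        raise ValueError(f"no reward defined for kind {kind}")

    def as_array(self) -> np.ndarray:
        """(2, 2) array indexed [kind - 1, cooperative] for the kernels."""
        return np.array(
            [[self.hare_solo, self.hare_coop], [self.stag_solo, self.stag_coop]],
            dtype=np.float64,
        )


#: Baseline rewards: no payoff at all for a stag hunted alone.
BASELINE_REWARDS = RewardTable(50.0, 50.0, 0.0, 500.0)
#: Variant in which a solo stag pays the same as a hare (no risk).
STAG_ALONE_REWARDS = RewardTable(50.0, 50.0, 50.0, 500.0)


@dataclass(frozen=True)
class ControllerConfig:
    """Feed-forward controller architecture and actuation scaling."""

    n_hidden: int = 8
    w_max: float = 5.0  # weights decoded into [-w_max, +w_max]
    v_max: float = 2.0  # wheel speed bound, length-units/step

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ConfigError("n_hidden must be >= 1")
        if self.w_max <= 0 or self.v_max <= 0:
            raise ConfigError("w_max and v_max must be positive")


@dataclass(frozen=True)
class EvoConfig:
    """Evolutionary-algorithm and episode parameters."""

    population_size: int = 20
    generations: int = 3000
    n_partners: int = 5
    sims_per_pair: int = 5
    gene_mutation_prob: float = 5e-3
    mutation_sigma: float = 0.1
    clonal: bool = False
    episode_steps: int = 20000
    capture_steps: int = 800
    catch_distance: float = 28.0
    n_hares: int = 9
    n_stags: int = 9
    seed: int = 0
    pre_generations: int = 1000
    partner_replacement: bool = True
    cumulative_capture: bool = False

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        if not 1 <= self.n_partners <= self.population_size - 1:
            raise ConfigError("n_partners must be in [1, population_size - 1]")
        if not 0.0 <= self.gene_mutation_prob <= 1.0:
            raise ConfigError("gene_mutation_prob must be in [0, 1]")
        if self.mutation_sigma < 0:
            raise ConfigError("mutation_sigma must be >= 0")
        for name in ("generations", "sims_per_pair", "episode_steps",
                     "capture_steps", "pre_generations"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.catch_distance <= 0:
            raise ConfigError("catch_distance must be positive")
        if self.n_hares < 0 or self.n_stags < 0:
            raise ConfigError("prey counts must be >= 0")
        if self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")

    @property
    def n_prey(self) -> int:
        return self.n_hares + self.n_stags

    @property
    def episodes_per_individual(self) -> int:
        return self.n_partners * self.sims_per_pair


_SECTION_TYPES = {
    "arena": ArenaConfig,
    "body": BodySpec,
    "rewards": RewardTable,
    "controller": ControllerConfig,
    "evo": EvoConfig,
}

#: Named reward presets addressable from config documents.
REWARD_PRESETS = {
    "baseline": BASELINE_REWARDS,
    "stag-alone-reward": STAG_ALONE_REWARDS,
}


@dataclass(frozen=True)
class SimConfig:
    """Complete run configuration: arena + body + rewards + controller + EA."""

    arena: ArenaConfig = field(default_factory=ArenaConfig)
    body: BodySpec = field(default_factory=BodySpec)
    rewards: RewardTable = field(default_factory=RewardTable)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    evo: EvoConfig = field(default_factory=EvoConfig)
    condition: str = "baseline"

    def replace(self, **sections: Any) -> "SimConfig":
        """Return a copy with whole sections or fields-within-sections replaced.

        ``cfg.replace(evo=dict(n_hares=3))`` updates one field;
        ``cfg.replace(rewards=RewardTable(...))`` swaps a section.
        """
        out: dict[str, Any] = {}
        for name, value in sections.items():
            if name == "condition":
                out[name] = value
                continue
            if name not in _SECTION_TYPES:
                raise ConfigError(f"unknown configuration section: {name!r}")
            if isinstance(value, Mapping):
                out[name] = dataclasses.replace(getattr(self, name), **value)
            else:
                out[name] = value
        return dataclasses.replace(self, **out)

    def to_dict(self) -> dict[str, Any]:
        d = {name: dataclasses.asdict(getattr(self, name)) for name in _SECTION_TYPES}
        d["condition"] = self.condition
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


@dataclass
class AgentState:
    """Pose and identity of one agent (hunter headings only are meaningful)."""

    id: int
    kind: int
    position: tuple[float, float]
    heading: float = 0.0

    @property
    def kind_name(self) -> str:
        return KIND_NAMES[self.kind]


@dataclass(frozen=True)
class HuntEvent:
    """One prey removal.

    ``cooperative`` is true iff both hunters were in catching distance at
    the trigger step; each participant receives ``reward_per_hunter`` in
    full (rewards are not split).
    """

    time: int
    prey_kind: int
    cooperative: bool
    participants: tuple[int, ...]
    reward_per_hunter: float

    @property
    def prey_kind_name(self) -> str:
        return KIND_NAMES[self.prey_kind]

    def to_dict(self) -> dict[str, Any]:
        return {
            "time": self.time,
            "prey_kind": self.prey_kind_name,
            "cooperative": self.cooperative,
            "participants": list(self.participants),
            "reward_per_hunter": self.reward_per_hunter,
        }


def make_rng(seed: int, stream_label: str) -> np.random.Generator:
    """Return an independent, reproducible random stream.

    Identical ``(seed, stream_label)`` pairs give identical streams;
    distinct labels give statistically independent streams.  The label is
    folded into the seed entropy byte-by-byte so the mapping is stable
    across processes and Python hash randomisation.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    entropy = [int(seed)] + list(stream_label.encode("utf-8"))
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy)))


def derive_seed(rng: np.random.Generator) -> int:
    """Draw a 31-bit integer seed suitable for kernel-level RNG state."""
    return int(rng.integers(0, 2**31 - 1))


def _build_section(cls: type, name: str, data: Mapping[str, Any]) -> Any:
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    try:
        return cls(**data)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(f"invalid section {name!r}: {exc}") from exc


def load_config(source: str | Path | Mapping[str, Any] | None = None,
                condition: str | None = None) -> SimConfig:
    """Load and validate a full configuration.

    ``source`` may be a mapping, a YAML document, a path to one, or None
    (all defaults).  Sections are ``arena``, ``body``, ``rewards``,
    ``controller``, ``evo``; a top-level ``condition`` names the
    experimental condition.  ``rewards`` may also be a preset name.
    Omitted keys take the defaults, which reproduce the baseline
    condition (rewards 50/50/0/500, 18 prey, population 20).
    """
    from . import experiments  # deferred: experiments imports core

    if source is None:
        data: dict[str, Any] = {}
    elif isinstance(source, Mapping):
        data = dict(source)
    else:
        text = str(source)
        p = Path(text)
        # Heuristic: a short single-line string with no colon is a path.
        if "\n" not in text and ":" not in text:
            if not p.exists():
                raise ConfigError(f"config file not found: {text}")
            text = p.read_text()
        elif "\n" not in text and p.suffix in {".yml", ".yaml"} and p.exists():
            text = p.read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            data = {}
        elif isinstance(loaded, Mapping):
            data = dict(loaded)
        else:
            raise ConfigError("config document must be a mapping")

    unknown = set(data) - set(_SECTION_TYPES) - {"condition"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    cond = condition if condition is not None else data.get("condition", "baseline")
    if cond not in experiments.CONDITIONS:
        raise ConfigError(
            f"unknown condition {cond!r}; known: {sorted(experiments.CONDITIONS)}"
        )
    # Condition preset first, then the document's explicit keys on top.
    cfg = experiments.apply_condition(SimConfig(), cond)
    for name, cls in _SECTION_TYPES.items():
        raw = data.get(name, {})
        if name == "rewards" and isinstance(raw, str):
            if raw not in REWARD_PRESETS:
                raise ConfigError(f"unknown reward preset: {raw!r}")
            cfg = cfg.replace(rewards=REWARD_PRESETS[raw])
            continue
        if not isinstance(raw, Mapping):
            raise ConfigError(f"section {name!r} must be a mapping")
        if raw:
            _build_section(cls, name, raw)  # key/range validation with defaults
            cfg = cfg.replace(**{name: dict(raw)})
    return cfg
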