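"""Named experimental conditions, scale profiles, and run orchestration.

Each named condition pins down a reward table, a prey mix, the pairing
regime (random partners or clones), the initial population (random or
pre-evolved hare hunters), and which model runs (embodied or the
one-locus game-theoretic baseline); every condition differs from the
baseline only in those fields.

Two scale profiles exist: ``full`` uses the default study scale; ``desk`` is
a deliberately small configuration (200x200 arena, 2000-step episodes,
200-step capture window, 6 prey, population 10, 50 generations and 50
pre-evolution generations) for smoke tests and quick exploration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from . import evolution, gt_baseline, io
from .analysis import ConditionSummary, last_generation_summary
from .core import (BASELINE_REWARDS, STAG_ALONE_REWARDS, ConfigError,
                   SimConfig)

__all__ = ["Condition", "CONDITIONS", "apply_condition", "make_config",
           "run_experiment", "run_one", "PROFILES"]


@dataclass(frozen=True)
class Condition:
    """One named experimental condition."""

    name: str
    rewards: str = "baseline"           # reward preset name
    n_hares: int = 9
    n_stags: int = 9
    clonal: bool = False
    init: str = "pre-evolved-hare"      # or "random"
    model: str = "robotic"              # or "gt"


CONDITIONS: dict[str, Condition] = {c.name: c for c in [
    Condition("baseline"),
    Condition("gt-baseline", model="gt", init="all-hare"),
    Condition("random-init", init="random"),
    Condition("stag-alone-reward", rewards="stag-alone-reward"),
    Condition("clonal", clonal=True),
    Condition("density-6", n_hares=3, n_stags=3),
    Condition("density-30", n_hares=15, n_stags=15),
]}

PROFILES = ("full", "desk")

_REWARD_PRESETS = {"baseline": BASELINE_REWARDS,
                   "stag-alone-reward": STAG_ALONE_REWARDS}


def apply_condition(cfg: SimConfig, name: str) -> SimConfig:
    """Overlay a named condition's presets onto a configuration."""
    if name not in CONDITIONS:
        raise ConfigError(f"unknown condition {name!r}")
    c = CONDITIONS[name]
    return cfg.replace(
        condition=name,
        rewards=_REWARD_PRESETS[c.rewards],
        evo=dict(n_hares=c.n_hares, n_stags=c.n_stags, clonal=c.clonal),
    )


def apply_profile(cfg: SimConfig, profile: str) -> SimConfig:
    """Scale a configuration to the requested profile."""
    if profile not in PROFILES:
        raise ConfigError(f"unknown profile {profile!r}; known: {PROFILES}")
    if profile == "full":
        return cfg
    # Desk profile: shrink everything while keeping the prey ratio.
    n_hares = max(cfg.evo.n_hares // 3, 1) if cfg.evo.n_hares else 0
    n_stags = max(cfg.evo.n_stags // 3, 1) if cfg.evo.n_stags else 0
    return cfg.replace(
        arena=dict(width=200.0, height=200.0),
        evo=dict(episode_steps=2000, capture_steps=200,
                 population_size=10, generations=50, pre_generations=50,
                 n_hares=n_hares, n_stags=n_stags),
    )


def make_config(condition: str, profile: str = "full",
                base: SimConfig | None = None) -> SimConfig:
    """Configuration for a named condition at the given scale."""
    cfg = base if base is not None else SimConfig()
    return apply_profile(apply_condition(cfg, condition), profile)


def run_one(cfg: SimConfig, seed: int, progress_callback=None
            ) -> evolution.RunRecord:
    """One independent run of whichever model the condition names."""
    cond = CONDITIONS[cfg.condition]
    if cond.model == "gt":
        return gt_baseline.gt_evolve(cfg, seed=seed, initial="all-hare")
    if cond.init == "pre-evolved-hare":
        pop = evolution.pre_evolve_hare_only(cfg, seed=seed)
        init = evolution.Population(0, pop.genomes, pop.fitnesses)
    else:
        init = None
    return evolution.evolve(cfg, seed=seed, initial_population=init,
                            progress_callback=progress_callback)


def run_experiment(condition: str, n_runs: int, base_seed: int,
                   scale_profile: str = "full",
                   out_dir: str | Path | None = None,
                   base: SimConfig | None = None,
                   trajectories: bool = False,
                   progress_callback=None
                   ) -> tuple[list[evolution.RunRecord], ConditionSummary]:
    """Execute ``n_runs`` independent runs of a named condition.

    Run r uses seed ``base_seed + r``.  When ``out_dir`` is given, each
    run's per-generation metrics and final genomes are written under
    ``run_<r>/`` along with a machine-readable manifest and a
    condition-summary CSV, so a run is fully reconstructible from its
    manifest.
    """
    if base is not None and base.condition == condition:
        # base already carries the condition (e.g. manifest rerun): keep its
        # field values rather than re-imposing the preset.
        cfg = apply_profile(base, scale_profile)
    else:
        cfg = make_config(condition, scale_profile, base=base)
    records = []
    for r in range(n_runs):
        rec = run_one(cfg, base_seed + r, progress_callback=progress_callback)
        records.append(rec)
    summary = last_generation_summary(records, condition)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for r, rec in enumerate(records):
            run_dir = out / f"run_{r}"
            run_dir.mkdir(exist_ok=True)
            io.write_run_record(rec, run_dir)
        summary.per_run.to_csv(out / "summary.csv", index=False)
        summary.curves.to_csv(out / "curves.csv", index=False)
        manifest = {
            "condition": dataclasses.asdict(CONDITIONS[condition]),
            "profile": scale_profile,
            "n_runs": n_runs,
            "base_seed": base_seed,
            "seeds": [base_seed + r for r in range(n_runs)],
            "config": cfg.to_dict(),
            "package": "staghunt",
            "version": _package_version(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return records, summary


def rerun_from_manifest(manifest_path: str | Path, out_dir: str | Path
                        ) -> tuple[list[evolution.RunRecord], ConditionSummary]:
    """Reconstruct and re-execute an experiment from its manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg_dict = dict(manifest["config"])
    condition = cfg_dict.pop("condition")
    base = SimConfig().replace(**cfg_dict)
    return run_experiment(condition, manifest["n_runs"], manifest["base_seed"],
                          scale_profile="full",  # config already scaled
                          out_dir=out_dir, base=base)


def _package_version() -> str:
    try:
        from importlib.metadata import version
        return version("staghunt")
    except Exception:
        return "unknown"
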