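"""Plain-text readers/writers for run records, genomes, events, trajectories."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import HuntEvent, NAME_KINDS

__all__ = ["write_run_record", "read_run_record", "write_genomes",
           "read_genomes", "write_events_jsonl", "read_events_jsonl",
           "write_trajectories_csv", "read_trajectories_csv"]


def write_run_record(record, run_dir: str | Path) -> None:
    """Write one run: metrics.csv, genomes.csv, last_eval_counts.csv, meta."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    record.metrics.to_csv(run_dir / "metrics.csv", index=False)
    write_genomes(record.final_population.genomes, run_dir / "genomes.csv",
                  fitnesses=record.final_population.fitnesses)
    if record.last_eval_counts is not None:
        c = np.asarray(record.last_eval_counts)
        df = pd.DataFrame(c.reshape(-1, 3),
                          columns=["hares", "coop_stags", "solo_stags"])
        df.insert(0, "episode", np.tile(np.arange(c.shape[1]), c.shape[0]))
        df.insert(0, "individual", np.repeat(np.arange(c.shape[0]), c.shape[1]))
        df.to_csv(run_dir / "last_eval_counts.csv", index=False)
    meta = {"condition": record.condition, "seed": record.seed,
            "generations": record.n_generations}
    (run_dir / "run.json").write_text(json.dumps(meta, indent=2))


def read_run_record(run_dir: str | Path):
    """Read a run directory back into a RunRecord."""
    from .evolution import Population, RunRecord  # local: avoid cycle

    run_dir = Path(run_dir)
    metrics = pd.read_csv(run_dir / "metrics.csv")
    genomes, fitnesses = read_genomes(run_dir / "genomes.csv")
    meta = json.loads((run_dir / "run.json").read_text())
    counts = None
    counts_path = run_dir / "last_eval_counts.csv"
    if counts_path.exists():
        df = pd.read_csv(counts_path)
        n_ind = df["individual"].nunique()
        n_ep = df["episode"].nunique()
        counts = (df[["hares", "coop_stags", "solo_stags"]]
                  .to_numpy().reshape(n_ind, n_ep, 3))
    pop = Population(generation=meta["generations"] - 1, genomes=genomes,
                     fitnesses=fitnesses)
    return RunRecord(metrics=metrics, final_population=pop,
                     last_eval_counts=counts, condition=meta["condition"],
                     seed=meta["seed"])


def write_genomes(genomes: np.ndarray, path: str | Path,
                  fitnesses: np.ndarray | None = None,
                  arch=None, w_max: float | None = None) -> None:
    """One genome per row; a comment header records the architecture."""
    genomes = np.asarray(genomes)
    path = Path(path)
    with path.open("w") as fh:
        if arch is not None:
            fh.write(f"# architecture: {arch.n_inputs}-{arch.n_hidden}-"
                     f"{arch.n_outputs}, w_max={arch.w_max}\n")
        elif w_max is not None:
            fh.write(f"# w_max={w_max}\n")
        cols = [f"g{i}" for i in range(genomes.shape[1])]
        header = ",".join((["fitness"] if fitnesses is not None else []) + cols)
        fh.write(header + "\n")
        for i in range(genomes.shape[0]):
            row = [repr(float(g)) for g in genomes[i]]
            if fitnesses is not None:
                row = [repr(float(fitnesses[i]))] + row
            fh.write(",".join(row) + "\n")


def read_genomes(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (genomes, fitnesses); fitnesses are zeros if absent."""
    df = pd.read_csv(path, comment="#")
    if "fitness" in df.columns:
        fitnesses = df["fitness"].to_numpy()
        genomes = df.drop(columns="fitness").to_numpy()
    else:
        fitnesses = np.zeros(len(df))
        genomes = df.to_numpy()
    return genomes, fitnesses


def write_events_jsonl(events: list[HuntEvent], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for e in events:
            fh.write(json.dumps(e.to_dict()) + "\n")


def read_events_jsonl(path: str | Path) -> list[HuntEvent]:
    events = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        events.append(HuntEvent(
            time=d["time"], prey_kind=NAME_KINDS[d["prey_kind"]],
            cooperative=d["cooperative"],
            participants=tuple(d["participants"]),
            reward_per_hunter=d["reward_per_hunter"]))
    return events


def write_trajectories_csv(traj: np.ndarray, path: str | Path) -> None:
    """traj has shape (steps, 2, 3): per step and hunter (x, y, heading)."""
    traj = np.asarray(traj)
    rows = []
    for h in range(traj.shape[1]):
        df = pd.DataFrame(traj[:, h, :], columns=["x", "y", "heading"])
        df.insert(0, "hunter", h)
        df.insert(0, "step", np.arange(traj.shape[0]))
        rows.append(df)
    pd.concat(rows).sort_values(["step", "hunter"]).to_csv(path, index=False)


def read_trajectories_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    n_steps = df["step"].nunique()
    n_hunters = df["hunter"].nunique()
    out = np.empty((n_steps, n_hunters, 3))
    for h in range(n_hunters):
        sub = df[df["hunter"] == h].sort_values("step")
        out[:, h, :] = sub[["x", "y", "heading"]].to_numpy()
    return out
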