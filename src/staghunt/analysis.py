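"""Metrics, cross-run aggregation, and statistical comparisons.

The headline metric throughout is the percentage of stags hunted
successfully (i.e. cooperatively) out of the total number of prey
hunted.  The denominator includes failed solo stag hunts: a stag killed
by a single hunter is removed from the arena, so it is a hunted prey
even when it rewards nothing.  (Set ``include_failed=False`` for the
alternative convention.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ConditionSummary", "stag_proportion", "last_generation_summary",
           "mann_whitney_u", "circling_statistic"]


@dataclass
class ConditionSummary:
    """Aggregate of one experimental condition across independent runs.

    ``per_run`` has one row per run: last-generation stag percentage and
    the mean and standard deviation, over that generation's episodes, of
    each hunted-prey category.  ``curves`` holds the per-generation stag
    percentage of every run plus their cross-run mean.
    """

    condition: str
    per_run: pd.DataFrame
    curves: pd.DataFrame


def stag_proportion(counts: tuple[float, float, float],
                    include_failed: bool = True) -> float:
    """Percentage of hunted prey that were cooperatively hunted stags.

    ``counts`` is (hares, cooperative stags, solo stags).  Returns
    100 * coop / (hares + coop [+ solo]); 0 when nothing was hunted.
    """
    hares, coop, solo = counts
    if min(hares, coop, solo) < 0:
        raise ValueError("counts must be non-negative")
    denom = hares + coop + (solo if include_failed else 0)
    if denom == 0:
        return 0.0
    return 100.0 * coop / denom


def last_generation_summary(run_records, condition: str | None = None
                            ) -> ConditionSummary:
    """Per-run last-generation statistics and cross-run metric curves.

    Each record must expose ``metrics`` (per-generation DataFrame with a
    ``stag_pct`` column) and ``last_eval_counts`` with shape
    (individuals, episodes, 3).  Per run, categories are averaged over
    all last-generation episodes (population x episodes); the summary
    stag percentage applies :func:`stag_proportion` to the summed
    counts.  Aggregation is independent of run order.
    """
    records = list(run_records)
    if not records:
        raise ValueError("need at least one completed run")
    if condition is None:
        condition = getattr(records[0], "condition", "unknown")
    rows = []
    curve_cols = {}
    for r, rec in enumerate(records):
        counts = np.asarray(rec.last_eval_counts).reshape(-1, 3)
        totals = counts.sum(axis=0)
        rows.append({
            "run": r,
            "stag_pct": stag_proportion(tuple(totals)),
            "mean_hares": counts[:, 0].mean(),
            "sd_hares": counts[:, 0].std(),
            "mean_coop_stags": counts[:, 1].mean(),
            "sd_coop_stags": counts[:, 1].std(),
            "mean_solo_stags": counts[:, 2].mean(),
            "sd_solo_stags": counts[:, 2].std(),
        })
        curve_cols[f"run_{r}"] = rec.metrics["stag_pct"].to_numpy()
    per_run = pd.DataFrame(rows)
    curves = pd.DataFrame(curve_cols)
    curves.insert(0, "generation", np.arange(len(curves)))
    curves["mean_stag_pct"] = curves.drop(columns="generation").mean(axis=1)
    return ConditionSummary(condition=condition, per_run=per_run, curves=curves)


def mann_whitney_u(sample_a, sample_b, method: str = "auto"
                   ) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p-value.

    U is the rank-sum statistic of sample a (midranks for ties).  With
    the default ``method="auto"`` the p-value is exact (full null
    enumeration) when n_a + n_b <= 12 and there are no ties, and
    otherwise uses the normal approximation with tie and continuity
    corrections; ``"exact"`` and ``"asymptotic"`` force one mode.
    Degenerate comparisons where every pooled value is identical return
    p = 1.
    """
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)
    has_ties = np.unique(pooled).size < pooled.size

    if method == "exact" or (method == "auto" and not has_ties
                             and n_a + n_b <= 12):
        if has_ties:
            raise ValueError("exact method requires tie-free samples")
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact").pvalue)
        return u_a, p

    # Normal approximation with tie correction and continuity correction.
    mu = n_a * n_b / 2.0
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u_a, 1.0
    z = (abs(u_a - mu) - 0.5) / math.sqrt(var)
    if z < 0:
        z = 0.0
    p = 2.0 * stats.norm.sf(z)
    return u_a, min(1.0, float(p))


def _wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    return -((-theta + np.pi) % (2.0 * np.pi) - np.pi)


def circling_statistic(traj_a: np.ndarray, traj_b: np.ndarray) -> float:
    """Mean absolute angular velocity of the partner bearing (rad/step).

    Quantifies mutual circling: per step the bearing from hunter A's
    position to hunter B's is computed, successive bearing increments are
    wrapped into (-pi, pi], and the statistic is the mean absolute
    increment, symmetrised over the two hunters.  Mutual orbiting yields
    the orbital angular speed; stationary hunters or straight parallel
    motion yield 0.  Steps where the hunters coincide contribute 0.
    """
    a = np.asarray(traj_a, dtype=np.float64)[:, :2]
    b = np.asarray(traj_b, dtype=np.float64)[:, :2]
    if a.shape != b.shape:
        raise ValueError("trajectories must have equal length")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 steps")

    def one_way(p, q):
        d = q - p
        coincident = (d[:, 0] == 0) & (d[:, 1] == 0)
        theta = np.arctan2(d[:, 1], d[:, 0])
        inc = _wrap_angle(np.diff(theta))
        bad = coincident[1:] | coincident[:-1]
        inc = np.where(bad, 0.0, inc)
        return float(np.mean(np.abs(inc)))

    return 0.5 * (one_way(a, b) + one_way(b, a))
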