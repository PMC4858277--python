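"""Single-locus game-theoretic stag hunt under the same evolutionary regime.

Here a strategy is one binary locus — hunt hares or hunt stags — and a
"simulation" is a single bout: a hare player always collects the hare
reward; a stag player collects the cooperative stag reward iff its
partner also plays stag, and otherwise the solo reward (the stag still
counts as a hunted prey, i.e. a failed hunt).  Evaluation (5 partner
draws x 5 bouts each), Wright-Fisher selection and the cooperative-hunt
metric reuse the exact machinery of the embodied model, so the two
models differ only in the genotype-phenotype map.

Also provides the replicator-dynamics invasion threshold: the cooperator
frequency at which, under random matching, the expected stag payoff
equals the hare payoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import stag_proportion
from .core import RewardTable, SimConfig, make_rng
from .evolution import (METRIC_COLUMNS, Population, RunRecord,
                        wright_fisher_select)

__all__ = ["HARE", "STAG", "GTBoutOutcome", "gt_bout", "gt_evolve",
           "replicator_threshold"]

HARE = 0
STAG = 1


@dataclass(frozen=True)
class GTBoutOutcome:
    """One player's side of a bout: what it hunted and what it earned."""

    strategy: int            # HARE or STAG
    success: bool            # False only for a stag attempted alone
    payoff: float
    cooperative: bool


def gt_bout(strategy_a: int, strategy_b: int, reward_table: RewardTable
            ) -> tuple[GTBoutOutcome, GTBoutOutcome]:
    """Play one stag-hunt bout; outcomes are symmetric under player swap."""

    def outcome(s, partner):
        if s == HARE:
            return GTBoutOutcome(HARE, True, reward_table.hare_solo, False)
        if partner == STAG:
            return GTBoutOutcome(STAG, True, reward_table.stag_coop, True)
        # A failed hunt: the stag is still a hunted prey, reward per table.
        return GTBoutOutcome(STAG, False, reward_table.stag_solo, False)

    for s in (strategy_a, strategy_b):
        if s not in (HARE, STAG):
            raise ValueError(f"invalid strategy {s!r}")
    return outcome(strategy_a, strategy_b), outcome(strategy_b, strategy_a)


def _initial_strategies(initial, size: int,
                        rng: np.random.Generator) -> np.ndarray:
    if isinstance(initial, np.ndarray):
        return np.array(initial, dtype=np.int64, copy=True)
    if initial == "all-hare":
        return np.zeros(size, dtype=np.int64)
    if initial == "all-stag":
        return np.ones(size, dtype=np.int64)
    if initial == "all-random":
        return rng.integers(0, 2, size=size)
    raise ValueError(f"unknown initialisation {initial!r}")


def gt_evolve(config: SimConfig, seed: int | None = None,
              initial="all-hare", generations: int | None = None,
              mutation_prob: float | None = None) -> RunRecord:
    """Evolve the one-locus population; record the stag metric per generation.

    Fitness is the mean bout payoff over n_partners x sims_per_pair
    bouts (each partner drawn uniformly among the others, never self).
    Selection is the shared Wright-Fisher sampler; mutation flips the
    locus with probability ``gene_mutation_prob`` per individual per
    generation.  The metric — successful stag hunts out of all prey
    hunted, failed solo attempts included — matches the embodied model's
    definition, with each focal bout contributing one hunted prey.
    """
    evo = config.evo
    if seed is None:
        seed = evo.seed
    n_gen = evo.generations if generations is None else generations
    if mutation_prob is None:
        mutation_prob = evo.gene_mutation_prob
    size = evo.population_size

    init_rng = make_rng(seed, "gt:init")
    strategies = _initial_strategies(initial, size, init_rng)
    if strategies.shape[0] != size:
        raise ValueError("initial strategies do not match population_size")

    eval_rng = make_rng(seed, "gt:eval")
    sel_rng = make_rng(seed, "gt:select")
    mut_rng = make_rng(seed, "gt:mutate")
    payoff = np.array(
        [[config.rewards.hare_solo, config.rewards.hare_solo],
         [config.rewards.stag_solo, config.rewards.stag_coop]])

    rows = []
    fitnesses = np.zeros(size)
    counts = None
    for g in range(n_gen):
        fitnesses, counts = _evaluate_gt_generation(
            strategies, payoff, evo.n_partners, evo.sims_per_pair, eval_rng)
        totals = counts.reshape(-1, 3).sum(axis=0)
        n_ep = counts.shape[0] * counts.shape[1]
        rows.append({
            "generation": g,
            "mean_fitness": float(fitnesses.mean()),
            "stag_pct": stag_proportion(tuple(totals)),
            "mean_hares": float(totals[0] / n_ep),
            "mean_coop_stags": float(totals[1] / n_ep),
            "mean_solo_stags": float(totals[2] / n_ep),
        })
        if g < n_gen - 1:
            parents = wright_fisher_select(fitnesses, sel_rng)
            strategies = strategies[parents]
            flips = mut_rng.random(size) < mutation_prob
            strategies = np.where(flips, 1 - strategies, strategies)
    metrics = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    final = Population(generation=max(n_gen - 1, 0),
                       genomes=strategies.astype(np.float64).reshape(-1, 1),
                       fitnesses=fitnesses)
    return RunRecord(metrics=metrics, final_population=final,
                     last_eval_counts=counts, condition="gt-baseline",
                     seed=seed)


def _evaluate_gt_generation(strategies: np.ndarray, payoff: np.ndarray,
                            n_partners: int, sims_per_pair: int,
                            rng: np.random.Generator
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised evaluation: each row draws its partners uniformly from
    the others (with replacement across draws), then plays sims_per_pair
    deterministic bouts per draw."""
    size = strategies.shape[0]
    eps = n_partners * sims_per_pair
    draws = rng.integers(0, size - 1, size=(size, n_partners))
    draws = draws + (draws >= np.arange(size)[:, None])  # skip self
    partners = np.repeat(draws, sims_per_pair, axis=1)   # (size, eps)
    s_i = strategies[:, None]
    s_j = strategies[partners]
    fitnesses = payoff[s_i, s_j].mean(axis=1)
    counts = np.zeros((size, eps, 3), dtype=np.int64)
    counts[:, :, 0] = s_i == HARE
    counts[:, :, 1] = (s_i == STAG) & (s_j == STAG)
    counts[:, :, 2] = (s_i == STAG) & (s_j == HARE)
    return fitnesses, counts


def replicator_threshold(reward_table: RewardTable) -> float:
    """Invasion threshold p* of the stag strategy under random matching.

    With cooperator frequency p, a stag player expects
    p * stag_coop + (1 - p) * stag_solo and a hare player hare_solo;
    equating the two gives
    p* = (hare_solo - stag_solo) / (stag_coop - stag_solo).
    Above p* selection favours stag hunting.  Requires
    stag_coop > hare_solo >= stag_solo for an interior (or boundary)
    threshold.
    """
    r = reward_table
    if not (r.stag_coop > r.hare_solo >= r.stag_solo):
        raise ValueError(
            "no invasion threshold: need stag_coop > hare_solo >= stag_solo")
    return (r.hare_solo - r.stag_solo) / (r.stag_coop - r.stag_solo)
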