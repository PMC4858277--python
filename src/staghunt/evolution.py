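"""Wright-Fisher neuroevolution of hunter controllers.

Each generation, every individual is evaluated by pairing: it plays
``n_partners`` randomly drawn partners (never itself; a fresh draw each
time, so the same partner can recur) for ``sims_per_pair`` episodes
each, and its fitness is its own payoff summed over all episodes and
divided by the episode count.  The next generation is formed by
fitness-proportionate sampling of parents (Wright-Fisher: offspring are
mutated clones, no recombination, no elitism).  Mutation perturbs each
gene independently with a small probability by a Gaussian draw, clipped
back into [0, 1].

Clonal mode pairs every individual with an identical copy of itself
(genetic relatedness 1) instead of drawing partners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .analysis import stag_proportion
from .controller import ControllerArchitecture, random_genome
from .core import SimConfig, make_rng

__all__ = ["Population", "RunRecord", "evaluate_fitness",
           "wright_fisher_select", "mutate", "evolve", "pre_evolve_hare_only"]

METRIC_COLUMNS = ["generation", "mean_fitness", "stag_pct",
                  "mean_hares", "mean_coop_stags", "mean_solo_stags"]


@dataclass
class Population:
    """One generation: genomes with (optionally) their evaluated fitnesses."""

    generation: int
    genomes: np.ndarray        # (population_size, genome_length)
    fitnesses: np.ndarray      # (population_size,)

    @property
    def size(self) -> int:
        return self.genomes.shape[0]


@dataclass
class RunRecord:
    """Per-generation metrics plus the final-generation snapshot.

    ``metrics`` has one row per evaluated generation: mean fitness, the
    percentage of prey hunts that were cooperative stag hunts, and mean
    per-episode counts of hares, cooperative stags and solo (failed)
    stags.  ``last_eval_counts`` holds the last generation's raw
    per-individual, per-episode category counts for summary statistics.
    """

    metrics: pd.DataFrame
    final_population: Population
    last_eval_counts: np.ndarray | None = field(default=None, repr=False)
    condition: str = "baseline"
    seed: int | None = None

    @property
    def n_generations(self) -> int:
        return len(self.metrics)


def _draw_partner(index: int, size: int, rng: np.random.Generator) -> int:
    """Uniform over all individuals except ``index``."""
    j = int(rng.integers(size - 1))
    return j + 1 if j >= index else j


def evaluate_fitness(index: int, population: np.ndarray, config: SimConfig,
                     rng: np.random.Generator,
                     counts_out: np.ndarray | None = None) -> float:
    """Fitness of one individual: mean own payoff per episode.

    Draws ``n_partners`` partners (each draw uniform over the others,
    with replacement across draws; in clonal mode the partner is always
    an identical copy of the focal genome) and runs ``sims_per_pair``
    episodes per pairing.  Only the focal individual's payoff — it is
    always hunter 0 — counts.  ``counts_out`` of shape (episodes, 3)
    receives per-episode (hares, coop stags, solo stags) counts.
    """
    evo = config.evo
    size = population.shape[0]
    if not evo.clonal and size < 2:
        raise ValueError("non-clonal evaluation needs a population of >= 2")
    partner_pool: list[int] | None = None
    if not evo.clonal and not evo.partner_replacement:
        others = [j for j in range(size) if j != index]
        partner_pool = list(rng.permutation(others)[:evo.n_partners])
    total = 0.0
    ep = 0
    for p in range(evo.n_partners):
        if evo.clonal:
            j = index
        elif partner_pool is not None:
            j = partner_pool[p % len(partner_pool)]
        else:
            j = _draw_partner(index, size, rng)
        for _ in range(evo.sims_per_pair):
            res = engine.run_episode(population[index], population[j], config, rng)
            total += float(res.payoffs[0])
            if counts_out is not None:
                counts_out[ep] = res.counts
            ep += 1
    return total / (evo.n_partners * evo.sims_per_pair)


def wright_fisher_select(fitnesses: np.ndarray, rng: np.random.Generator
                         ) -> np.ndarray:
    """One parent index per offspring slot, P(i) = f_i / sum(f).

    Draws are independent (non-overlapping generations).  All-zero
    fitnesses fall back to uniform sampling.
    """
    f = np.asarray(fitnesses, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("fitnesses must be non-negative")
    n = f.shape[0]
    total = f.sum()
    if total <= 0:
        return rng.integers(0, n, size=n)
    return rng.choice(n, size=n, p=f / total)


def mutate(genome: np.ndarray, config: SimConfig, rng: np.random.Generator
           ) -> np.ndarray:
    """Gaussian per-gene mutation, clipped to [0, 1]; parent unmodified.

    Each gene independently, with probability ``gene_mutation_prob``,
    receives an additive Normal(0, mutation_sigma**2) perturbation.
    """
    evo = config.evo
    out = np.array(genome, dtype=np.float64, copy=True)
    mask = rng.random(out.shape[0]) < evo.gene_mutation_prob
    k = int(mask.sum())
    if k:
        out[mask] += rng.normal(0.0, evo.mutation_sigma, size=k)
        np.clip(out, 0.0, 1.0, out=out)
    return out


def _evaluate_generation(genomes: np.ndarray, config: SimConfig,
                         rng: np.random.Generator
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Fitnesses and per-individual per-episode counts for one generation."""
    size = genomes.shape[0]
    eps = config.evo.episodes_per_individual
    fitnesses = np.empty(size)
    counts = np.zeros((size, eps, 3), dtype=np.int64)
    for i in range(size):
        fitnesses[i] = evaluate_fitness(i, genomes, config, rng,
                                        counts_out=counts[i])
    return fitnesses, counts


def _metric_row(generation: int, fitnesses: np.ndarray, counts: np.ndarray
                ) -> dict:
    totals = counts.reshape(-1, 3).sum(axis=0)
    n_episodes = counts.shape[0] * counts.shape[1]
    return {
        "generation": generation,
        "mean_fitness": float(fitnesses.mean()),
        "stag_pct": stag_proportion(tuple(totals)),
        "mean_hares": float(totals[0] / n_episodes),
        "mean_coop_stags": float(totals[1] / n_episodes),
        "mean_solo_stags": float(totals[2] / n_episodes),
    }


def evolve(config: SimConfig, seed: int | None = None,
           initial_population: Population | np.ndarray | None = None,
           generations: int | None = None,
           progress_callback=None, stream_prefix: str = "") -> RunRecord:
    """Run the full evolutionary loop and record per-generation metrics.

    Generation g is evaluated and recorded, then (except after the last
    recorded generation) parents are drawn by Wright-Fisher selection and
    each offspring is a mutated clone.  With ``generations = 0`` only the
    initial snapshot is returned.  All randomness derives from labelled
    substreams of ``seed`` (default ``config.evo.seed``), so identical
    inputs give identical records.
    """
    evo = config.evo
    if seed is None:
        seed = evo.seed
    n_gen = evo.generations if generations is None else generations
    arch = ControllerArchitecture.from_config(config.body, config.controller)

    if initial_population is None:
        init_rng = make_rng(seed, stream_prefix + "init")
        genomes = np.stack([random_genome(arch, init_rng)
                            for _ in range(evo.population_size)])
    else:
        genomes = (initial_population.genomes
                   if isinstance(initial_population, Population)
                   else np.asarray(initial_population))
        genomes = np.array(genomes, dtype=np.float64, copy=True)
        if genomes.shape != (evo.population_size, arch.genome_length):
            raise ValueError(
                f"initial population shape {genomes.shape} does not match "
                f"({evo.population_size}, {arch.genome_length})")

    eval_rng = make_rng(seed, stream_prefix + "eval")
    sel_rng = make_rng(seed, stream_prefix + "select")
    mut_rng = make_rng(seed, stream_prefix + "mutate")

    rows: list[dict] = []
    fitnesses = np.zeros(evo.population_size)
    counts = None
    for g in range(n_gen):
        fitnesses, counts = _evaluate_generation(genomes, config, eval_rng)
        rows.append(_metric_row(g, fitnesses, counts))
        if progress_callback is not None:
            progress_callback(g, rows[-1])
        if g < n_gen - 1:
            parents = wright_fisher_select(fitnesses, sel_rng)
            genomes = np.stack([mutate(genomes[p], config, mut_rng)
                                for p in parents])
    metrics = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    final = Population(generation=max(n_gen - 1, 0), genomes=genomes,
                       fitnesses=fitnesses)
    return RunRecord(metrics=metrics, final_population=final,
                     last_eval_counts=counts, condition=config.condition,
                     seed=seed)


def pre_evolve_hare_only(config: SimConfig, seed: int | None = None,
                         generations: int | None = None,
                         progress_callback=None) -> Population:
    """Evolve in a hare-only world to seed a solitary-equilibrium start.

    The prey total is preserved but every prey is a hare; the run lasts
    ``pre_generations`` (configurable) and the final population is
    returned to pass straight into :func:`evolve` as its initial
    population, without re-randomisation.
    """
    hare_cfg = config.replace(evo=dict(n_hares=config.evo.n_prey, n_stags=0))
    if generations is None:
        generations = config.evo.pre_generations
    if seed is None:
        seed = config.evo.seed
    rec = evolve(hare_cfg, seed=seed, generations=generations,
                 progress_callback=progress_callback, stream_prefix="pre:")
    return rec.final_population
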