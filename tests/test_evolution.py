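"""Pairing-based evaluation, Wright-Fisher selection, mutation, evolve loop."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import staghunt.evolution as evo_mod
from staghunt.engine import EpisodeResult
from staghunt.evolution import (Population, evaluate_fitness, evolve, mutate,
                                pre_evolve_hare_only, wright_fisher_select)


@pytest.fixture()
def stub_episodes(monkeypatch):
    """Replace episode simulation with a constant-payoff stub; log pairings."""
    calls = []

    def fake_run_episode(ga, gb, config, rng, record_trajectories=False):
        calls.append((ga, gb))
        return EpisodeResult(payoffs=np.array([100.0, 60.0]), events=[],
                             n_hares=2, n_coop_stags=0, n_solo_stags=0)

    monkeypatch.setattr(evo_mod.engine, "run_episode", fake_run_episode)
    return calls


class TestEvaluateFitness:
    def test_constant_payoffs_mean_and_episode_count(self, tiny_config,
                                                     stub_episodes, rng):
        cfg = tiny_config.replace(evo=dict(population_size=20, n_partners=5,
                                           sims_per_pair=5))
        pop = rng.random((20, 506))
        counts = np.zeros((25, 3), dtype=np.int64)
        f = evaluate_fitness(0, pop, cfg, rng, counts_out=counts)
        assert f == 100.0  # only the focal hunter's payoff counts
        assert len(stub_episodes) == 25
        assert np.all(counts[:, 0] == 2)

    def test_partner_never_self_in_random_mode(self, tiny_config,
                                               stub_episodes, rng):
        cfg = tiny_config.replace(evo=dict(population_size=6, n_partners=3))
        pop = rng.random((6, 506))
        evaluate_fitness(2, pop, cfg, rng)
        for ga, gb in stub_episodes:
            assert np.shares_memory(ga, pop[2])
            assert not np.shares_memory(gb, pop[2])

    def test_clonal_mode_pairs_with_identical_copy(self, tiny_config,
                                                   stub_episodes, rng):
        cfg = tiny_config.replace(evo=dict(clonal=True))
        pop = rng.random((4, 506))
        evaluate_fitness(1, pop, cfg, rng)
        assert stub_episodes
        for ga, gb in stub_episodes:
            assert np.array_equal(ga, gb)


class TestWrightFisher:
    def test_single_nonzero_fitness_takes_all(self, rng):
        f = np.zeros(20)
        f[0] = 7.0
        assert np.all(wright_fisher_select(f, rng) == 0)

    def test_negative_fitness_rejected(self, rng):
        with pytest.raises(ValueError):
            wright_fisher_select(np.array([1.0, -0.1]), rng)

    def test_zero_total_falls_back_to_uniform(self, rng):
        picks = wright_fisher_select(np.zeros(20), rng)
        assert picks.shape == (20,)
        assert np.all((picks >= 0) & (picks < 20))

    def test_equal_fitness_draws_uniform(self, rng):
        draws = np.concatenate([wright_fisher_select(np.ones(20), rng)
                                for _ in range(5000)])  # 100 000 draws
        counts = np.bincount(draws, minlength=20)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_one_to_three_fitness_ratio(self, rng):
        f = np.array([1.0, 3.0])
        draws = np.concatenate([wright_fisher_select(f, rng)
                                for _ in range(50000)])  # 100 000 draws
        freq = draws.mean()
        se = np.sqrt(0.75 * 0.25 / draws.size)
        assert abs(freq - 0.75) < 3 * se


class TestMutate:
    def test_zero_probability_is_identity(self, tiny_config, rng):
        cfg = tiny_config.replace(evo=dict(gene_mutation_prob=0.0))
        g = rng.random(506)
        assert np.array_equal(mutate(g, cfg, rng), g)

    def test_parent_unmodified_and_output_clipped(self, tiny_config, rng):
        cfg = tiny_config.replace(evo=dict(gene_mutation_prob=1.0,
                                           mutation_sigma=2.0))
        g = np.concatenate([np.zeros(253), np.ones(253)])
        g0 = g.copy()
        m = mutate(g, cfg, rng)
        assert np.array_equal(g, g0)
        assert np.all((m >= 0.0) & (m <= 1.0))
        assert not np.array_equal(m, g)

    def test_touch_rate_matches_binomial_expectation(self, tiny_config, rng):
        cfg = tiny_config.replace(evo=dict(gene_mutation_prob=5e-3,
                                           mutation_sigma=0.1))
        g = np.full(506, 0.5)
        touched = [np.sum(mutate(g, cfg, rng) != g) for _ in range(10000)]
        mean = np.mean(touched)
        expected = 506 * 5e-3
        se = np.sqrt(506 * 5e-3 * (1 - 5e-3) / 10000)
        assert abs(mean - expected) < 3 * se


class TestEvolve:
    def test_zero_generations_returns_initial_snapshot_only(self, tiny_config):
        rec = evolve(tiny_config, seed=0, generations=0)
        assert rec.n_generations == 0
        assert rec.final_population.genomes.shape == (4, 506)

    def test_records_every_generation_and_is_deterministic(self, tiny_config):
        r1 = evolve(tiny_config, seed=3)
        r2 = evolve(tiny_config, seed=3)
        assert r1.n_generations == tiny_config.evo.generations
        assert r1.metrics.equals(r2.metrics)
        assert np.array_equal(r1.final_population.genomes,
                              r2.final_population.genomes)
        assert r1.last_eval_counts.shape == (4, 2, 3)

    def test_population_size_constant_and_offspring_are_copies(self,
                                                               tiny_config):
        rec = evolve(tiny_config, seed=5)
        assert rec.final_population.size == tiny_config.evo.population_size
        # Elitism-free: final genomes are fresh arrays, not aliased rows.
        g = rec.final_population.genomes
        assert g.base is None or g.base is not g

    def test_metrics_within_ranges(self, tiny_config):
        m = evolve(tiny_config, seed=1).metrics
        assert ((m["stag_pct"] >= 0) & (m["stag_pct"] <= 100)).all()
        assert (m[["mean_hares", "mean_coop_stags", "mean_solo_stags"]]
                >= 0).all().all()
        assert (m["mean_fitness"] >= 0).all()

    def test_wrong_initial_population_shape_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="shape"):
            evolve(tiny_config, seed=0,
                   initial_population=np.zeros((3, 506)))


class TestPreEvolve:
    def test_prey_composition_is_hares_only(self, tiny_config, monkeypatch):
        seen = {}
        real_evolve = evo_mod.evolve

        def spy(config, **kwargs):
            seen["n_hares"] = config.evo.n_hares
            seen["n_stags"] = config.evo.n_stags
            return real_evolve(config, **kwargs)

        monkeypatch.setattr(evo_mod, "evolve", spy)
        pop = pre_evolve_hare_only(tiny_config, seed=0, generations=1)
        assert seen == {"n_hares": 4, "n_stags": 0}
        assert isinstance(pop, Population)

    def test_population_passes_through_without_rerandomisation(self,
                                                               tiny_config):
        pop = pre_evolve_hare_only(tiny_config, seed=0, generations=1)
        rec = evolve(tiny_config, seed=0, generations=0,
                     initial_population=pop)
        assert np.array_equal(rec.final_population.genomes, pop.genomes)
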