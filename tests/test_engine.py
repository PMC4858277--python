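"""Arena physics, ray casting, capture rules, and the episode loop."""

import numpy as np
import pytest
from scipy import stats

import staghunt as sh
from staghunt.core import KIND_HARE, KIND_NONE, KIND_STAG
from staghunt.engine import (cast_ray, place_agents, resolve_collisions,
                             run_episode, step_hunter, update_captures)
from staghunt.fixtures import build_fixture

from helpers import (assert_world_invariants, oracle_cast_ray, random_world,
                     run_episode_stepwise)


class TestPlacement:
    def test_separation_and_wall_clearance(self, default_config):
        w = place_agents(default_config, np.random.default_rng(0))
        assert_world_invariants(w, 9, 9)
        pos = w.positions
        d = np.hypot(pos[:, None, 0] - pos[None, :, 0],
                     pos[:, None, 1] - pos[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 14.0
        assert pos.min() >= 7.0 and pos.max() <= 793.0

    def test_same_seed_identical(self, default_config):
        a = place_agents(default_config, np.random.default_rng(5))
        b = place_agents(default_config, np.random.default_rng(5))
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.headings, b.headings)

    def test_single_agent_positions_uniform_over_quadrants(self, default_config):
        cfg = default_config.replace(evo=dict(n_hares=0, n_stags=0))
        rng = np.random.default_rng(11)
        xs = np.empty((10000, 2))
        for i in range(10000):
            xs[i] = place_agents(cfg, rng).positions[0]
        # Quadrants of the admissible square [7, 793]^2.
        mid = 400.0
        counts = [np.sum((xs[:, 0] < mid) & (xs[:, 1] < mid)),
                  np.sum((xs[:, 0] < mid) & (xs[:, 1] >= mid)),
                  np.sum((xs[:, 0] >= mid) & (xs[:, 1] < mid)),
                  np.sum((xs[:, 0] >= mid) & (xs[:, 1] >= mid))]
        assert stats.chisquare(counts).pvalue > 0.01

    def test_overcrowded_arena_raises(self, default_config):
        cramped = default_config.replace(arena=dict(width=40.0, height=40.0))
        with pytest.raises(RuntimeError, match="crowded"):
            place_agents(cramped, np.random.default_rng(0))


class TestKinematics:
    def test_straight_motion(self, default_config):
        w = build_fixture("hunter-alone-center", default_config)
        w.positions[0] = (100.0, 100.0)
        w.headings[0] = 0.0
        step_hunter(w, 0, (1.0, 1.0))
        assert np.allclose(w.positions[0], (101.0, 100.0))
        assert w.headings[0] == 0.0

    def test_pure_rotation(self, default_config):
        w = build_fixture("hunter-alone-center", default_config)
        p0 = w.positions[0].copy()
        h0 = w.headings[0]
        step_hunter(w, 0, (-0.5, 0.5))
        assert np.allclose(w.positions[0], p0)
        assert np.isclose(w.headings[0], h0 + 2 * 0.5 / 14.0)

    def test_wall_clamp_preserves_heading(self, default_config):
        w = build_fixture("hunter-alone-center", default_config)
        w.positions[0] = (8.0, 400.0)
        w.headings[0] = np.pi  # driving into the left wall
        step_hunter(w, 0, (2.0, 2.0))
        assert w.positions[0][0] == 7.0
        assert w.positions[0][1] == 400.0
        assert np.isclose(w.headings[0], np.pi)

    def test_corner_trap_clamps_both_axes(self, default_config):
        w = build_fixture("corner-trap", default_config)
        for _ in range(40):
            step_hunter(w, 0, (2.0, 2.0))
        assert np.allclose(w.positions[0], (7.0, 7.0))


class TestCollisions:
    def test_push_out_to_exact_contact(self, default_config):
        w = build_fixture("two-hunters-flanking-prey", default_config)
        prey = w.positions[2].copy()
        w.positions[0] = prey + (10.0, 0.0)  # overlapping the prey disk
        resolve_collisions(w, 0)
        d = np.hypot(*(w.positions[0] - prey))
        assert np.isclose(d, 14.0, atol=1e-9)
        assert np.array_equal(w.positions[2], prey)  # prey never moves

    def test_no_contact_no_motion(self, default_config):
        w = build_fixture("hunter-alone-center", default_config)
        p0 = w.positions[0].copy()
        resolve_collisions(w, 0)
        assert np.array_equal(w.positions[0], p0)


class TestCastRay:
    def test_closed_form_disk_distance(self, default_config):
        w = build_fixture("hunter-facing-stag-at-50", default_config)
        ox, oy = w.positions[0]
        kind, t = cast_ray(w, (ox - 50.0, oy), 0.0, exclude_id=0)
        # Stag centre is 100 from this origin, radius 7 -> first hit at 93.
        assert kind == KIND_STAG
        assert np.isclose(t, 93.0, atol=1e-9)

    def test_empty_direction_reports_wall(self, default_config):
        w = build_fixture("hunter-alone-center", default_config)
        kind, t = cast_ray(w, (400.0, 400.0), np.pi / 2, exclude_id=0)
        assert kind == KIND_NONE
        assert np.isclose(t, 400.0)

    def test_nearer_of_two_disks_wins(self, default_config):
        w = build_fixture("two-hunters-flanking-prey", default_config)
        w.positions[0] = (100.0, 400.0)
        w.positions[1] = (150.0, 400.0)   # hunter at 50
        w.positions[2] = (180.0, 400.0)   # stag at 80
        kind, t = cast_ray(w, (100.0, 400.0), 0.0, exclude_id=0)
        assert kind == 0  # the nearer disk is the other hunter
        assert np.isclose(t, 43.0)

    def test_agreement_with_exhaustive_oracle(self, desk_config):
        rng = np.random.default_rng(3)
        n_scenes = 1000
        for _ in range(n_scenes):
            w = random_world(desk_config, rng)
            angle = rng.random() * 2 * np.pi
            origin = tuple(w.positions[0])
            got = cast_ray(w, origin, angle, exclude_id=0)
            want = oracle_cast_ray(w, origin, angle, exclude_id=0)
            assert got[0] == want[0]
            assert abs(got[1] - want[1]) < 1e-6


class TestCaptures:
    def test_solo_capture_after_800_consecutive_steps(self, default_config):
        cfg = default_config
        w = build_fixture("one-hunter-on-hare", cfg)
        rng = np.random.default_rng(0)
        events = []
        for _ in range(800):
            events.extend(update_captures(w, cfg.rewards, rng=rng))
        assert len(events) == 1
        e = events[0]
        assert e.prey_kind == KIND_HARE and not e.cooperative
        assert e.participants == (0,)
        assert e.reward_per_hunter == 50.0
        assert e.time == 799  # 800th step, 0-indexed

    def test_solo_stag_is_a_failed_hunt_worth_zero(self, default_config):
        w = build_fixture("two-hunters-flanking-prey", default_config)
        w.positions[1] = (700.0, 700.0)  # second hunter far away
        rng = np.random.default_rng(0)
        payoffs = np.zeros(2)
        events = []
        for _ in range(800):
            events.extend(update_captures(w, default_config.rewards,
                                          rng=rng, payoffs=payoffs))
        assert len(events) == 1
        assert events[0].prey_kind == KIND_STAG
        assert not events[0].cooperative
        assert events[0].reward_per_hunter == 0.0
        assert np.array_equal(payoffs, (0.0, 0.0))

    def test_partner_arriving_at_final_step_makes_it_cooperative(
            self, default_config):
        w = build_fixture("two-hunters-flanking-prey", default_config)
        prey = w.positions[2].copy()
        far = np.array((700.0, 700.0))
        w.positions[1] = far
        rng = np.random.default_rng(0)
        payoffs = np.zeros(2)
        events = []
        for _ in range(799):
            events.extend(update_captures(w, default_config.rewards,
                                          rng=rng, payoffs=payoffs))
        assert not events
        w.positions[1] = prey + (20.0, 0.0)  # arrives for the final step
        events.extend(update_captures(w, default_config.rewards,
                                      rng=rng, payoffs=payoffs))
        assert len(events) == 1
        assert events[0].cooperative
        assert events[0].participants == (0, 1)
        assert events[0].reward_per_hunter == 500.0
        assert np.array_equal(payoffs, (500.0, 500.0))

    def test_counter_resets_when_no_hunter_in_range(self, default_config):
        w = build_fixture("one-hunter-on-hare", default_config)
        home = w.positions[0].copy()
        rng = np.random.default_rng(0)
        for _ in range(400):
            update_captures(w, default_config.rewards, rng=rng)
        assert w.counters[0] == 400
        w.positions[0] = (700.0, 100.0)  # leaves range
        update_captures(w, default_config.rewards, rng=rng)
        assert w.counters[0] == 0
        w.positions[0] = home
        events = []
        for _ in range(799):
            events.extend(update_captures(w, default_config.rewards, rng=rng))
        assert not events  # the clock restarted

    def test_cumulative_mode_does_not_reset(self, default_config):
        cfg = default_config.replace(evo=dict(cumulative_capture=True))
        w = build_fixture("one-hunter-on-hare", cfg)
        rng = np.random.default_rng(0)
        for _ in range(400):
            update_captures(w, cfg.rewards, rng=rng)
        w.positions[0] = (700.0, 100.0)
        update_captures(w, cfg.rewards, rng=rng)
        assert w.counters[0] == 400

    def test_capture_respawns_same_kind_elsewhere(self, default_config):
        w = build_fixture("one-hunter-on-hare", default_config)
        before = w.positions[2].copy()
        rng = np.random.default_rng(0)
        events = []
        for _ in range(800):
            events.extend(update_captures(w, default_config.rewards, rng=rng))
        assert len(events) == 1
        assert w.prey_counts() == (1, 0)
        assert not np.array_equal(w.positions[2], before)
        assert w.counters[0] == 0
        assert_world_invariants(w, 1, 0)


class TestRunEpisode:
    def test_zero_prey_zero_payoffs(self, desk_config):
        cfg = desk_config.replace(evo=dict(n_hares=0, n_stags=0,
                                           episode_steps=500))
        g = np.random.default_rng(0).random((2, 506))
        res = run_episode(g[0], g[1], cfg, 0)
        assert np.array_equal(res.payoffs, (0.0, 0.0))
        assert res.events == []

    def test_deterministic_given_seed(self, tiny_config):
        g = np.random.default_rng(1).random((2, 506))
        r1 = run_episode(g[0], g[1], tiny_config, 42, record_trajectories=True)
        r2 = run_episode(g[0], g[1], tiny_config, 42, record_trajectories=True)
        assert np.array_equal(r1.payoffs, r2.payoffs)
        assert r1.events == r2.events
        assert np.array_equal(r1.trajectories, r2.trajectories)

    def test_payoff_ledger_matches_events(self, desk_config):
        cfg = desk_config.replace(evo=dict(episode_steps=3000, capture_steps=150))
        rng = np.random.default_rng(9)
        for trial in range(5):
            g = rng.random((2, 506))
            res = run_episode(g[0], g[1], cfg, int(rng.integers(2**31)))
            for h in range(2):
                ledger = sum(e.reward_per_hunter for e in res.events
                             if h in e.participants)
                assert res.payoffs[h] == ledger

    def test_stepwise_driver_reproduces_compiled_episode(self, tiny_config):
        """The public per-step operations and the compiled loop are one path."""
        cfg = tiny_config.replace(evo=dict(episode_steps=400, capture_steps=40))
        g = np.random.default_rng(2).random((2, 506))
        res = run_episode(g[0], g[1], cfg, 7)
        payoffs, events, _ = run_episode_stepwise(
            g[0], g[1], cfg, np.random.default_rng(7), check_every=10)
        assert np.array_equal(payoffs, res.payoffs)
        assert events == res.events

    def test_hare_only_payoffs_are_multiples_of_50(self, desk_config):
        cfg = desk_config.replace(evo=dict(n_hares=6, n_stags=0,
                                           episode_steps=2000))
        rng = np.random.default_rng(4)
        for trial in range(3):
            g = rng.random((2, 506))
            res = run_episode(g[0], g[1], cfg, trial)
            assert np.all(np.mod(res.payoffs, 50.0) == 0)
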