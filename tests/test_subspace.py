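"""Marginalization, residual extraction and the generalization test."""

import numpy as np
import pytest

from multisense.stats import ConfidenceInterval, ConfigError, SufficientStats
from multisense.subspace import (
    SourceKey,
    StatTables,
    enumerate_sources,
    intervals_intersect,
    project,
    residual_stats,
)


class TestSourceEnumeration:
    def test_two_sensors_powerset_is_just_singletons(self):
        assert enumerate_sources(2, powerset=True) == [SourceKey((1,)), SourceKey((2,))]

    def test_three_sensors_powerset_counts_proper_subsets(self):
        sources = enumerate_sources(3, powerset=True)
        assert len(sources) == 6  # 2^3 - 2
        assert SourceKey((1, 3)) in sources and SourceKey((1, 2, 3)) not in sources

    def test_three_sensors_default_singletons(self):
        assert enumerate_sources(3) == [SourceKey((i,)) for i in (1, 2, 3)]

    def test_single_sensor_has_no_proper_subspaces(self):
        assert enumerate_sources(1) == []

    def test_invalid_k(self):
        with pytest.raises(ConfigError):
            enumerate_sources(0)


class TestProjection:
    @pytest.mark.parametrize(
        "source,expected",
        [((2,), (12,)), ((1, 3), (7, 3)), ((1, 2, 3), (7, 12, 3))],
    )
    def test_projection_examples(self, source, expected):
        assert project((7, 12, 3), SourceKey(source)) == expected


class TestRecordExperience:
    def test_single_experience_updates_all_tables(self):
        t = StatTables(k=2, n_positions=5, n_actions=3)
        t.record_experience((2, 4), 1, 0.5)
        assert t.joint_cell((2, 4), 1).n == 1
        for src in t.sources:
            assert t.marginal_cell(src, (2, 4), 1).n == 1
        # other cells untouched
        assert t.joint_cell((2, 3), 1).n == 0

    def test_marginal_pools_states_sharing_an_observation(self):
        t = StatTables(k=2, n_positions=5, n_actions=2)
        for _ in range(2):
            t.record_experience((1, 2), 0, 1.0)
        for _ in range(3):
            t.record_experience((1, 4), 0, 0.0)
        assert t.marginal_cell(SourceKey((1,)), (1, 2), 0).n == 5
        assert t.marginal_cell(SourceKey((2,)), (1, 2), 0).n == 2

    def test_incremental_marginals_equal_brute_force(self, rng):
        """Exact equivalence with from-scratch marginalization of the joint table."""
        n_pos, n_act, k = 4, 3, 3
        t = StatTables(k=k, n_positions=n_pos, n_actions=n_act, sources=enumerate_sources(k, powerset=True))
        experiences = []
        for _ in range(1000):
            state = tuple(rng.integers(1, n_pos + 1, size=k))
            action = int(rng.integers(n_act))
            r = float(rng.uniform())
            t.record_experience(state, action, r)
            experiences.append((state, action, r))
        for src in t.sources:
            cells: dict = {}
            for state, action, r in experiences:
                key = (project(state, src), action)
                n, sr, sr2 = cells.get(key, (0, 0.0, 0.0))
                cells[key] = (n + 1, sr + r, sr2 + r * r)
            for (obs, action), (n, sr, sr2) in cells.items():
                state = tuple(obs[src.sensor_indices.index(i)] if i in src.sensor_indices else 1 for i in range(1, k + 1))
                cell = t.marginal_cell(src, state, action)
                assert cell.n == n  # counts integer-exact
                assert cell.sum_r == pytest.approx(sr, abs=1e-9)
                assert cell.sum_r2 == pytest.approx(sr2, abs=1e-9)

    def test_out_of_range_reward_propagates(self):
        t = StatTables(k=2, n_positions=5, n_actions=2)
        with pytest.raises(Exception):
            t.record_experience((1, 1), 0, 2.0)


class TestResiduals:
    def test_componentwise_subtraction(self):
        res = residual_stats(SufficientStats(5, 3.0, 2.2), SufficientStats(3, 2.0, 1.5))
        assert (res.n, res.sum_r) == (2, 1.0)
        assert res.sum_r2 == pytest.approx(0.7)
        assert res.sum_r / res.n == 0.5

    def test_marginal_equal_joint_gives_empty_residual(self):
        res = residual_stats(SufficientStats(4, 2.0, 1.1), SufficientStats(4, 2.0, 1.1))
        assert res == SufficientStats(0, 0.0, 0.0)

    def test_inconsistent_tables_detected(self):
        with pytest.raises(ValueError):
            residual_stats(SufficientStats(2, 1.0, 0.5), SufficientStats(3, 2.0, 1.5))

    def test_residual_plus_joint_recovers_marginal_after_random_run(self, rng):
        t = StatTables(k=2, n_positions=4, n_actions=3)
        for _ in range(600):
            state = tuple(rng.integers(1, 5, size=2))
            t.record_experience(state, int(rng.integers(3)), float(rng.uniform()))
        for state in [(a, b) for a in range(1, 5) for b in range(1, 5)]:
            for action in range(3):
                joint = t.joint_cell(state, action)
                for src in t.sources:
                    res = t.residual_cell(src, state, action)
                    marg = t.marginal_cell(src, state, action)
                    assert res.n + joint.n == marg.n
                    assert res.sum_r + joint.sum_r == pytest.approx(marg.sum_r, abs=1e-9)


class TestIntervalIntersection:
    def make(self, lo, up):
        return ConfidenceInterval(lo, up, "student_t", 0.05)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0.1, 0.4), (0.3, 0.8), True),
            ((0.0, 0.2), (0.5, 0.9), False),
            ((0.0, 0.5), (0.5, 1.0), True),  # closed intervals: touching counts
            ((-np.inf, np.inf), (0.9, 0.95), True),
        ],
    )
    def test_examples(self, a, b, expected):
        assert intervals_intersect(self.make(*a), self.make(*b)) is expected
        assert intervals_intersect(self.make(*b), self.make(*a)) is expected  # symmetric


class TestGeneralizationTest:
    def fill(self, tables, state, action, rewards):
        for r in rewards:
            tables.record_experience(state, action, r)

    def test_cold_start_always_accepts(self):
        t = StatTables(k=2, n_positions=5, n_actions=2)
        accept, b_hat, m = t.g_test((1, 1), SourceKey((1,)), 0)
        assert accept and b_hat.is_unbounded and m.is_unbounded

    def test_garbage_aliasing_rejected(self, rng):
        """Two states aliased on sensor 1 with opposite deterministic rewards."""
        t = StatTables(k=2, n_positions=5, n_actions=2)
        self.fill(t, (1, 1), 0, [1.0] * 150)
        self.fill(t, (1, 2), 0, [0.0] * 150)
        accept, b_hat, m = t.g_test((1, 1), SourceKey((1,)), 0)
        assert not accept
        # degenerate point intervals at the two means
        assert m.lower == m.upper == 1.0
        assert b_hat.lower == b_hat.upper == 0.0
        # sensor 2 does not alias these states, so its residual is empty: accept
        assert t.g_test((1, 1), SourceKey((2,)), 0)[0]

    def test_rejection_rate_grows_with_evidence(self, rng):
        """Noisy garbage aliasing: rejection frequency approaches 1 past ~100 samples."""
        rejections = {25: 0, 200: 0}
        reps = 60
        for n in rejections:
            for _ in range(reps):
                t = StatTables(k=2, n_positions=5, n_actions=1)
                self.fill(t, (1, 1), 0, (rng.uniform(size=n) < 0.9).astype(float))
                self.fill(t, (1, 2), 0, (rng.uniform(size=n) < 0.1).astype(float))
                if not t.g_test((1, 1), SourceKey((1,)), 0)[0]:
                    rejections[n] += 1
        assert rejections[200] >= 0.95 * reps
        assert rejections[200] >= rejections[25]

    def test_true_generalization_retained(self, rng):
        """States aliased on a sensor with identical reward distributions keep passing."""
        alpha, reps, accepted = 0.05, 200, 0
        for _ in range(reps):
            t = StatTables(k=2, n_positions=5, n_actions=1)
            self.fill(t, (1, 1), 0, (rng.uniform(size=500) < 0.6).astype(float))
            self.fill(t, (1, 2), 0, (rng.uniform(size=500) < 0.6).astype(float))
            if t.g_test((1, 1), SourceKey((1,)), 0, alpha=alpha)[0]:
                accepted += 1
        assert accepted / reps >= 1 - 2 * alpha


class TestSerialization:
    def test_json_round_trip(self, rng, tmp_path):
        t = StatTables(k=2, n_positions=4, n_actions=3)
        for _ in range(200):
            t.record_experience(tuple(rng.integers(1, 5, size=2)), int(rng.integers(3)), float(rng.uniform()))
        path = tmp_path / "tables.json"
        t.save_json(path)
        t2 = StatTables.load_json(path)
        assert np.array_equal(t._joint["n"], t2._joint["n"])
        assert np.allclose(t._joint["sum_r2"], t2._joint["sum_r2"])
        for a, b in zip(t._marg, t2._marg):
            assert np.allclose(a["sum_r"], b["sum_r"])
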