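import itertools
import math

import numpy as np
import pandas as pd
import pytest

import herdmove as hm
from herdmove.leadership import LeadershipMatrix


def wiggly(n, seed=0, scale=0.4):
    """A heading series with ongoing variation (so windows have variance)."""
    rng = np.random.default_rng(seed)
    return np.mod(np.cumsum(rng.normal(0, scale, n)), 2 * math.pi)


class TestDyadLagScore:
    def test_follower_with_known_lag(self):
        h = wiggly(200, seed=1)
        hi, hj = h[4:], h[:-4]  # hj(t) = hi(t - 4): j trails i
        n = min(hi.size, hj.size)
        _, scores = hm.dyad_lag_score(hi[:n], hj[:n])
        scored = scores[scores != 0]
        assert scored.size > 0
        assert (scored == 1).mean() > 0.9  # i leads almost everywhere

    def test_identical_series_neutral(self):
        h = wiggly(120, seed=2)
        _, scores = hm.dyad_lag_score(h, h.copy())
        assert np.all(scores == 0)

    def test_uncorrelated_noise_below_threshold(self):
        rng = np.random.default_rng(3)
        a = np.mod(rng.normal(0, 3, 150), 2 * math.pi)
        b = np.mod(rng.normal(0, 3, 150), 2 * math.pi)
        _, scores = hm.dyad_lag_score(a, b)
        assert (scores == 0).mean() > 0.8

    def test_antisymmetry(self):
        hi = wiggly(150, seed=4)
        hj = np.roll(hi, 3)
        _, s_ij = hm.dyad_lag_score(hi, hj)
        _, s_ji = hm.dyad_lag_score(hj, hi)
        np.testing.assert_array_equal(s_ij, -s_ji)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            hm.dyad_lag_score(np.ones(20), np.ones(20))


class TestBuildMatrix:
    def _table_with_leader(self, lag=3, n=320, n_agents=4, seed=0):
        """a00 is a persistent initiator: everyone else copies its heading
        trace with increasing delay."""
        base = np.unwrap(wiggly(n + 40, seed=seed))
        rows = []
        for i in range(n_agents):
            h = np.mod(base[20 - i * lag:20 - i * lag + n], 2 * math.pi)
            for t in range(n):
                rows.append({"time_s": t, "individual_id": f"a{i:02d}",
                             "x_m": float(i), "y_m": 0.0, "heading_rad": h[t]})
        return hm.TrajectoryTable.from_frame(pd.DataFrame(rows))

    def test_single_dyad_counts(self):
        table = self._table_with_leader(n_agents=2)
        ev = hm.DecisionEvent(event_id="e", day_id="d0", t_departure_s=200,
                              window=(100, 300))
        m = hm.build_matrix([ev], table, "departure")
        a, b = m.ids.index("a00"), m.ids.index("a01")
        assert m.scores[a, b] > 0
        assert m.scores[b, a] == 0

    def test_symmetric_input_symmetric_matrix(self):
        h = wiggly(320, seed=9)
        rows = []
        for i in range(2):
            for t in range(320):
                rows.append({"time_s": t, "individual_id": f"a{i}",
                             "x_m": float(i), "y_m": 0.0, "heading_rad": h[t]})
        table = hm.TrajectoryTable.from_frame(pd.DataFrame(rows))
        ev = hm.DecisionEvent(event_id="e", day_id="d0", t_departure_s=200,
                              window=(100, 300))
        m = hm.build_matrix([ev], table, "departure")
        np.testing.assert_array_equal(m.scores, m.scores.T)

    def test_persistent_initiator_highest_row_sum(self):
        table = self._table_with_leader(n_agents=4)
        ev = hm.DecisionEvent(event_id="e", day_id="d0", t_departure_s=200,
                              window=(100, 300))
        m = hm.build_matrix([ev], table, "departure")
        row_sums = m.scores.sum(axis=1)
        assert np.argmax(row_sums) == m.ids.index("a00")
        nds = hm.norm_david_score(m)
        assert max(nds, key=nds.get) == "a00"

    def test_no_retained_events_rejected(self, small_table):
        ev = hm.DecisionEvent(event_id="e", day_id="d0", t_departure_s=10,
                              window=(0, 20), excluded_reason="no_stationary")
        with pytest.raises(ValueError):
            hm.build_matrix([ev], small_table, "departure")


def linear_hierarchy_matrix(n, weight=12):
    m = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = weight
    return LeadershipMatrix(ids=[f"g{i}" for i in range(n)], scores=m,
                            phase="departure")


class TestNormDavidScore:
    def test_linear_hierarchy_strictly_decreasing(self):
        nds = hm.norm_david_score(linear_hierarchy_matrix(6))
        vals = [nds[f"g{i}"] for i in range(6)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_symmetric_matrix_all_equal(self):
        m = LeadershipMatrix(ids=["a", "b", "c"],
                             scores=np.array([[0, 5, 5], [5, 0, 5], [5, 5, 0]]),
                             phase="departure")
        nds = hm.norm_david_score(m)
        assert len(set(round(v, 9) for v in nds.values())) == 1

    def test_three_individual_textbook_oracle(self):
        # wins: A beats B 8-2, A beats C 6-4, B beats C 7-3
        scores = np.array([[0, 8, 6], [2, 0, 7], [4, 3, 0]])
        m = LeadershipMatrix(ids=["A", "B", "C"], scores=scores, phase="departure")
        nds = hm.norm_david_score(m)

        # independent textbook computation with explicit loops
        n = 3
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                nij = scores[i, j] + scores[j, i]
                pij = scores[i, j] / nij
                d[i, j] = pij - (pij - 0.5) / (nij + 1)
        w = d.sum(axis=1)
        w2 = np.array([sum(d[i, j] * w[j] for j in range(n)) for i in range(n)])
        l = d.sum(axis=0)
        l2 = np.array([sum(d[j, i] * l[j] for j in range(n)) for i in range(n)])
        expected = (w + w2 - l - l2 + n * (n - 1) / 2) / n
        for k, ind in enumerate(["A", "B", "C"]):
            assert nds[ind] == pytest.approx(expected[k], abs=1e-12)

    def test_all_zero_degenerate(self):
        m = LeadershipMatrix(ids=["a", "b"], scores=np.zeros((2, 2), dtype=int),
                             phase="departure")
        nds = hm.norm_david_score(m)
        assert nds["a"] == nds["b"]


class TestTriangleTransitivity:
    @pytest.mark.parametrize("n", [5, 7, 10])
    def test_strict_hierarchy_t_tri_one(self, n):
        t_tri, p = hm.triangle_transitivity(linear_hierarchy_matrix(n),
                                            n_perm=100, seed=0)
        assert t_tri == pytest.approx(1.0)
        assert 0 < p <= 1

    def test_three_cycle_minus_three(self):
        scores = np.array([[0, 12, 0], [0, 0, 12], [12, 0, 0]])
        m = LeadershipMatrix(ids=["a", "b", "c"], scores=scores, phase="departure")
        t_tri, _ = hm.triangle_transitivity(m, n_perm=100, seed=0)
        assert t_tri == pytest.approx(-3.0)

    def test_random_tournaments_mean_near_zero(self):
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(60):
            n = 6
            scores = np.zeros((n, n), dtype=int)
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.5:
                    scores[i, j] = 12
                else:
                    scores[j, i] = 12
            m = LeadershipMatrix(ids=[str(k) for k in range(n)],
                                 scores=scores, phase="departure")
            t_tri, _ = hm.triangle_transitivity(m, n_perm=1, seed=0)
            vals.append(t_tri)
        assert abs(np.mean(vals)) < 0.3

    def test_sparse_dyads_excluded(self):
        # counts below the threshold leave no complete triangle
        scores = np.array([[0, 3, 3], [0, 0, 3], [0, 0, 0]])
        m = LeadershipMatrix(ids=["a", "b", "c"], scores=scores, phase="departure")
        t_tri, p = hm.triangle_transitivity(m, n_perm=10, seed=0,
                                            min_dyad_total=10)
        assert math.isnan(t_tri) and math.isnan(p)


class TestDirectionalConsistency:
    def test_fully_one_directional(self):
        dc, _ = hm.directional_consistency(linear_hierarchy_matrix(4),
                                           n_perm=50, seed=0)
        assert dc == pytest.approx(1.0)

    def test_balanced_dyads_zero(self):
        scores = np.array([[0, 6], [6, 0]])
        m = LeadershipMatrix(ids=["a", "b"], scores=scores, phase="departure")
        dc, _ = hm.directional_consistency(m, n_perm=50, seed=0)
        assert dc == pytest.approx(0.0)

    def test_worked_example(self):
        # dyads (H, L) = (3, 1) and (2, 2) -> (2 + 0) / (4 + 4) = 0.25
        scores = np.array([[0, 3, 0], [1, 0, 2], [0, 2, 0]])
        m = LeadershipMatrix(ids=["a", "b", "c"], scores=scores, phase="departure")
        dc, _ = hm.directional_consistency(m, n_perm=50, seed=0)
        assert dc == pytest.approx(0.25)

    def test_empty_matrix_undefined(self):
        m = LeadershipMatrix(ids=["a", "b"], scores=np.zeros((2, 2), dtype=int),
                             phase="departure")
        dc, p = hm.directional_consistency(m, n_perm=10, seed=0)
        assert math.isnan(dc) and math.isnan(p)

    def test_relabeling_invariance(self):
        scores = np.array([[0, 9, 1], [3, 0, 5], [2, 6, 0]])
        perm = [2, 0, 1]
        m1 = LeadershipMatrix(ids=["a", "b", "c"], scores=scores, phase="departure")
        m2 = LeadershipMatrix(ids=["c", "a", "b"],
                              scores=scores[np.ix_(perm, perm)], phase="departure")
        dc1, _ = hm.directional_consistency(m1, n_perm=1, seed=0)
        dc2, _ = hm.directional_consistency(m2, n_perm=1, seed=0)
        assert dc1 == pytest.approx(dc2)


class TestPermutationValidity:
    def test_dc_p_uniform_under_null(self):
        # under the coin-flip null, p should be roughly uniform
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(80):
            scores = np.zeros((4, 4), dtype=int)
            for i, j in itertools.combinations(range(4), 2):
                w = rng.binomial(20, 0.5)
                scores[i, j], scores[j, i] = w, 20 - w
            m = LeadershipMatrix(ids=list("abcd"), scores=scores, phase="departure")
            _, p = hm.directional_consistency(m, n_perm=200,
                                              seed=int(rng.integers(2**31)))
            ps.append(p)
        ps = np.array(ps)
        assert 0.35 < ps.mean() < 0.75
        assert (ps < 0.25).mean() < 0.45

    def test_ttri_p_valid_under_null(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(60):
            scores = np.zeros((5, 5), dtype=int)
            for i, j in itertools.combinations(range(5), 2):
                if rng.random() < 0.5:
                    scores[i, j] = 15
                else:
                    scores[j, i] = 15
            m = LeadershipMatrix(ids=list("abcde"), scores=scores, phase="departure")
            _, p = hm.triangle_transitivity(m, n_perm=200,
                                            seed=int(rng.integers(2**31)))
            ps.append(p)
        ps = np.array(ps)
        # valid (possibly conservative) p-values: small p not over-produced
        assert (ps < 0.05).mean() <= 0.1
        assert ps.mean() > 0.3


def test_matrix_invariants_rejected():
    with pytest.raises(ValueError):
        LeadershipMatrix(ids=["a", "b"], scores=np.array([[1, 0], [0, 0]]),
                         phase="departure")
    with pytest.raises(ValueError):
        LeadershipMatrix(ids=["a"], scores=np.zeros((2, 2)), phase="departure")
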