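import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idiodyn.core_io import LongitudinalSeries
from idiodyn.recurrence import (
    UNCATEGORISED,
    UNIQUE,
    build_network,
    categorize_profiles,
    distance_matrix,
    profile_series,
    profile_summary,
    radius_for_rate,
    recurrence_structure,
    rqa_measures,
    strength_centrality,
)

from _oracles import oracle_rqa, oracle_strengths
from conftest import planted_markov


class TestProfileSeries:
    def test_raw_is_identity_on_complete_data(self, small_series):
        X, idx = profile_series(small_series)
        np.testing.assert_array_equal(X, small_series.values)
        np.testing.assert_array_equal(idx, [0, 1, 2, 3])

    def test_first_difference_arithmetic(self):
        s = LongitudinalSeries("s", [0, 1], ["a"], [[1.0], [4.0]])
        X, idx = profile_series(s, mode="first_difference")
        np.testing.assert_array_equal(X, [[3.0]])
        np.testing.assert_array_equal(idx, [1])

    def test_constant_series_differences_to_zero(self):
        s = LongitudinalSeries("s", np.arange(5), ["a"], np.full((5, 1), 3.0))
        X, _ = profile_series(s, mode="first_difference")
        np.testing.assert_array_equal(X, np.zeros((4, 1)))

    def test_incomplete_occasions_excluded(self):
        vals = np.array([[1.0, 2.0], [np.nan, 0.0], [3.0, 4.0]])
        s = LongitudinalSeries("s", [0, 1, 2], ["a", "b"], vals)
        X, idx = profile_series(s)
        np.testing.assert_array_equal(idx, [0, 2])
        np.testing.assert_array_equal(X, [[1.0, 2.0], [3.0, 4.0]])

    def test_constant_variable_cannot_standardise(self):
        s = LongitudinalSeries("s", [0, 1, 2], ["a"], [[1.0], [1.0], [1.0]])
        with pytest.raises(ValueError, match="constant"):
            profile_series(s, standardise="per_variable")


class TestDistanceMatrix:
    def test_three_four_five(self):
        D = distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D[0, 1] == pytest.approx(5.0)
        assert D[0, 0] == 0.0

    @pytest.mark.parametrize("metric,fn", [
        ("euclidean", lambda d: np.sqrt(np.sum(d ** 2))),
        ("manhattan", lambda d: np.sum(np.abs(d))),
        ("chebyshev", lambda d: np.max(np.abs(d))),
    ])
    def test_matches_pairwise_loop(self, rng, metric, fn):
        X = rng.normal(size=(5, 3))
        D = distance_matrix(X, metric=metric)
        for i in range(5):
            for j in range(5):
                assert D[i, j] == pytest.approx(fn(X[i] - X[j]))

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            distance_matrix(np.ones((1, 3)))


class TestRadiusForRate:
    def test_quantile_semantics(self, rng):
        X = rng.normal(size=(20, 2))
        D = distance_matrix(X)
        res = radius_for_rate(D, 0.05, theiler=1)
        i, j = np.triu_indices(20, k=2)
        d = np.sort(D[i, j])
        assert res.epsilon == d[int(np.ceil(0.05 * d.size)) - 1]
        assert abs(res.achieved_rr - 0.05) <= 1.0 / res.n_eligible

    def test_target_near_one_gives_full_recurrence(self, rng):
        D = distance_matrix(rng.normal(size=(10, 2)))
        res = radius_for_rate(D, 0.999, theiler=0)
        assert res.achieved_rr == 1.0

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.05, 0.5), st.floats(0.5, 0.95))
    def test_monotone_in_target(self, seed, lo, hi):
        D = distance_matrix(np.random.default_rng(seed).normal(size=(12, 2)))
        assert (radius_for_rate(D, lo).epsilon
                <= radius_for_rate(D, hi).epsilon)

    def test_identical_distances_advises_manual_radius(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        D = distance_matrix(X)   # equilateral triangle
        with pytest.raises(ValueError, match="manual"):
            radius_for_rate(D, 0.5, theiler=0)


class TestRecurrenceStructure:
    def test_hand_thresholding_on_toy(self):
        D = np.array([
            [0.0, 1.0, 4.0, 2.5],
            [1.0, 0.0, 1.5, 5.0],
            [4.0, 1.5, 0.0, 3.0],
            [2.5, 5.0, 3.0, 0.0],
        ])
        rs = recurrence_structure(D, epsilon=3.0, theiler=1)
        expected = np.zeros((4, 4), dtype=bool)
        expected[0, 2] = expected[2, 0] = False   # 4.0 > 3
        expected[0, 3] = expected[3, 0] = True    # 2.5
        expected[1, 3] = expected[3, 1] = False   # 5.0
        np.testing.assert_array_equal(rs.rec, expected)
        assert rs.weights[0, 3] == pytest.approx(1 - 2.5 / 3.0)
        assert rs.weights[0, 1] == 0.0            # inside Theiler band

    def test_epsilon_below_minimum_gives_none(self, rng):
        D = distance_matrix(rng.normal(size=(6, 2)))
        i, j = np.triu_indices(6, k=2)
        rs = recurrence_structure(D, epsilon=0.99 * D[i, j].min(), theiler=1)
        assert rs.rec.sum() == 0

    def test_epsilon_above_maximum_gives_all(self, rng):
        D = distance_matrix(rng.normal(size=(6, 2)))
        rs = recurrence_structure(D, epsilon=D.max() + 1, theiler=1)
        assert rs.rec.sum() == rs.eligible_mask().sum()
        assert np.all(rs.weights[rs.rec] >= 0)

    def test_theiler_wider_than_series_rejected(self):
        with pytest.raises(ValueError, match="theiler"):
            recurrence_structure(np.zeros((4, 4)), 1.0, theiler=4)


class TestRQA:
    def test_constant_series_fully_deterministic(self):
        # every pair recurs; apart from the length-1 corner diagonal the
        # classical line census puts all points on maximal diagonal lines
        D = np.zeros((30, 30))
        rs = recurrence_structure(D + 0.0, epsilon=1.0, theiler=1)
        m = rqa_measures(rs)
        assert m.recurrence_rate == 1.0
        oracle = oracle_rqa(D.tolist(), 1.0, 1)
        assert m.determinism == pytest.approx(oracle[1])
        assert m.determinism > 0.99

    def test_period_two_alternation_is_all_diagonal(self):
        x = np.array([0.0, 10.0] * 4)[:, None]
        D = distance_matrix(x)
        rs = recurrence_structure(D, epsilon=1.0, theiler=1)
        m = rqa_measures(rs)
        oracle = oracle_rqa(D.tolist(), 1.0, 1)
        assert m.determinism == pytest.approx(oracle[1]) == 1.0

    def test_no_recurrences_reported_missing(self, rng):
        D = distance_matrix(rng.normal(size=(6, 2)))
        i, j = np.triu_indices(6, k=2)
        rs = recurrence_structure(D, epsilon=0.9 * D[i, j].min(), theiler=1)
        m = rqa_measures(rs)
        assert m.recurrence_rate == 0.0
        assert np.isnan(m.determinism) and np.isnan(m.laminarity)

    def test_random_structures_match_oracle(self, rng):
        for _ in range(10):
            T = int(rng.integers(8, 25))
            X = rng.normal(size=(T, 2))
            D = distance_matrix(X)
            eps = radius_for_rate(D, float(rng.uniform(0.1, 0.4))).epsilon
            rs = recurrence_structure(D, eps, theiler=1)
            m = rqa_measures(rs)
            rr, det, lam, mean_line = oracle_rqa(D.tolist(), eps, 1)
            assert m.recurrence_rate == pytest.approx(rr)
            assert m.determinism == pytest.approx(det, nan_ok=True)
            assert m.laminarity == pytest.approx(lam, nan_ok=True)
            assert m.mean_line == pytest.approx(mean_line, nan_ok=True)


class TestNetwork:
    def test_no_recurrence_all_isolated(self):
        rs = recurrence_structure(np.full((4, 4), 9.0) - 9 * np.eye(4),
                                  epsilon=1.0, theiler=1)
        G = build_network(rs)
        assert G.number_of_edges() == 0
        assert all(s == 0.0 for s in strength_centrality(G).values())

    def test_strengths_equal_manual_sums(self, rng):
        X = rng.normal(size=(10, 2))
        D = distance_matrix(X)
        eps = radius_for_rate(D, 0.3).epsilon
        rs = recurrence_structure(D, eps, theiler=1)
        G = build_network(rs)
        s = strength_centrality(G)
        expected = oracle_strengths(D.tolist(), eps, 1)
        for i in range(10):
            assert s[i] == pytest.approx(expected[i])

    def test_star_centre_strength(self):
        G = nx.Graph()
        G.add_weighted_edges_from([(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)])
        s = strength_centrality(G)
        assert s[0] == 3.0 and s[1] == 1.0


class TestCategorisation:
    @staticmethod
    def _graph(edges, n):
        G = nx.Graph()
        G.add_nodes_from(range(n))
        G.add_weighted_edges_from(edges)
        return G

    def test_two_triangles_and_isolate(self):
        # triangle 0-1-2 (unit weights) outweighs triangle 3-4-5 (half);
        # node 6 never recurs
        edges = [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0),
                 (3, 4, 0.5), (4, 5, 0.5), (3, 5, 0.5)]
        lab = categorize_profiles(self._graph(edges, 7), k=4)
        assert lab.labels == ["class_1"] * 3 + ["class_2"] * 3 + [UNIQUE]
        assert lab.hub_ids == [0, 3]     # ties broken by earlier occasion

    def test_fully_connected_single_class(self):
        G = self._graph([(i, j, 1.0) for i in range(5) for j in range(i + 1, 5)], 5)
        lab = categorize_profiles(G, k=4)
        assert lab.labels == ["class_1"] * 5
        assert lab.hub_ids == [0]

    def test_empty_graph_all_unique(self):
        lab = categorize_profiles(self._graph([], 4), k=3)
        assert lab.labels == [UNIQUE] * 4
        assert lab.hub_ids == []

    def test_leftover_connected_nodes_uncategorised(self):
        # pair 3-4 is connected but unreachable as a hub with k=1
        edges = [(0, 1, 1.0), (0, 2, 1.0), (3, 4, 0.4)]
        lab = categorize_profiles(self._graph(edges, 5), k=1)
        assert lab.labels == ["class_1"] * 3 + [UNCATEGORISED] * 2

    def test_insertion_order_does_not_matter(self):
        edges = [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0), (3, 4, 0.5)]
        G1 = self._graph(edges, 5)
        G2 = self._graph(list(reversed(edges)), 5)
        assert (categorize_profiles(G1, k=2).labels
                == categorize_profiles(G2, k=2).labels)


class TestProfileSummary:
    def test_single_class_mean_is_grand_mean(self, rng):
        X = rng.normal(size=(6, 2))
        D = distance_matrix(X)
        rs = recurrence_structure(D, epsilon=D.max() + 1, theiler=0)
        lab = categorize_profiles(rs, k=1)
        tab = profile_summary(X, lab, variables=["a", "b"])
        assert len(tab) == 1
        assert tab.loc[0, "occupancy"] == 1.0
        np.testing.assert_allclose(tab.loc[0, ["a", "b"]].astype(float),
                                   X.mean(axis=0))

    def test_planted_profiles_recovered_within_2se(self):
        series, true = planted_markov(K=2, T=500, seed=42)
        X, occ = profile_series(series)
        D = distance_matrix(X)
        eps = radius_for_rate(D, 0.45).epsilon
        rs = recurrence_structure(D, eps, theiler=1)
        lab = categorize_profiles(rs, k=2)
        tab = profile_summary(X, lab, variables=series.variables)
        hub_states = [true[occ[h]] for h in lab.hub_ids]
        from idiodyn.synthetic import make_profiles
        planted = make_profiles(2, 6, min_distance=3.0 * 10 * np.sqrt(6))
        for row, state in zip(range(len(lab.hub_ids)), hub_states):
            got = tab.loc[tab["class"] == f"class_{row + 1}",
                          series.variables].to_numpy(dtype=float)[0]
            n = (np.asarray(lab.labels) == f"class_{row + 1}").sum()
            se = 10.0 / np.sqrt(n)
            # clipping to [0, 100] biases extreme profiles slightly inward,
            # so allow 2 SE plus a small clip allowance
            assert np.all(np.abs(got - planted[state]) < 2 * se + 1.0)
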