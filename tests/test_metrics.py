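"""Graph metrics vs brute-force oracles and analytic small cases."""

import networkx as nx
import numpy as np
import pytest

from conncompare.io import ValidationError
from conncompare.metrics import (characteristic_path_length,
                                 clustering_coefficient, compute_metric_set,
                                 degrees, global_efficiency, local_efficiency,
                                 modularity, normalized_metrics,
                                 random_reference, shortest_paths, strengths)
from oracles import (brute_char_path_length, brute_clustering,
                     brute_distance_matrix, brute_global_efficiency,
                     brute_local_efficiency, brute_max_modularity,
                     newman_modularity, random_connected_graph)


def complete_graph(n):
    return np.ones((n, n)) - np.eye(n)


def path_graph(n):
    m = np.zeros((n, n))
    for i in range(n - 1):
        m[i, i + 1] = m[i + 1, i] = 1.0
    return m


def ws_matrix(n=32, k=6, beta=0.1, seed=0):
    g = nx.watts_strogatz_graph(n, k, beta, seed=seed)
    return nx.to_numpy_array(g)


class TestShortestPaths:
    def test_complete_graph_unit_distances(self):
        d = shortest_paths(complete_graph(4), weighted=False)
        off = ~np.eye(4, dtype=bool)
        assert np.all(d[off] == 1)

    def test_path_graph_two_hops(self):
        d = shortest_paths(path_graph(3), weighted=False)
        assert d[0, 2] == 2

    def test_weighted_matches_brute_enumeration(self, rng):
        w = random_connected_graph(rng, 8, weighted=True)
        d = shortest_paths(w, weighted=True)
        assert np.allclose(d, brute_distance_matrix(w, True), atol=1e-10)


class TestCharacteristicPathLength:
    def test_complete_graph_is_one(self):
        assert characteristic_path_length(complete_graph(6), False) == 1.0

    def test_four_node_path_hand_value(self):
        assert characteristic_path_length(path_graph(4), False) == \
            pytest.approx(10.0 / 6.0)

    def test_watts_strogatz_matches_networkx(self):
        m = ws_matrix()
        ours = characteristic_path_length(m, weighted=False)
        theirs = nx.average_shortest_path_length(nx.from_numpy_array(m))
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_fully_disconnected_rejected(self):
        with pytest.raises(ValidationError):
            characteristic_path_length(np.zeros((4, 4)), False)


class TestClustering:
    def test_triangle_is_one(self):
        assert clustering_coefficient(complete_graph(3), False) == 1.0

    def test_star_is_zero(self):
        star = np.zeros((5, 5))
        star[0, 1:] = star[1:, 0] = 1.0
        assert clustering_coefficient(star, False) == 0.0

    def test_k4_minus_edge(self):
        m = complete_graph(4)
        m[0, 1] = m[1, 0] = 0.0
        # nodes 0,1 (degree 2, linked neighbors): C=1; nodes 2,3: C=2/3
        assert clustering_coefficient(m, False) == pytest.approx(5.0 / 6.0)

    def test_matches_triangle_enumeration(self, rng):
        a = random_connected_graph(rng, 8, weighted=False)
        assert clustering_coefficient(a, False) == \
            pytest.approx(brute_clustering(a, False), abs=1e-12)

    def test_weighted_matches_onnela_oracle(self, rng):
        w = random_connected_graph(rng, 8, weighted=True)
        assert clustering_coefficient(w, True) == \
            pytest.approx(brute_clustering(w, True), abs=1e-10)

    def test_weighted_reduces_to_binary_on_unit_weights(self, rng):
        a = random_connected_graph(rng, 7, weighted=False)
        assert clustering_coefficient(a, True) == \
            pytest.approx(clustering_coefficient(a, False), abs=1e-12)


class TestEfficiency:
    def test_complete_graph_global_is_one(self):
        assert global_efficiency(complete_graph(5), False) == 1.0

    def test_three_node_path_value(self):
        assert global_efficiency(path_graph(3), False) == \
            pytest.approx(5.0 / 6.0)

    def test_isolated_node_contributes_zero(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 1.0
        # pairs: (0,1)=1 both ways, node 2 unreachable -> 4 zero pairs
        assert global_efficiency(m, False) == pytest.approx(2.0 / 6.0)

    def test_k4_local_is_one(self):
        assert local_efficiency(complete_graph(4), False) == 1.0

    def test_star_local_is_zero(self):
        star = np.zeros((6, 6))
        star[0, 1:] = star[1:, 0] = 1.0
        assert local_efficiency(star, False) == 0.0

    def test_local_matches_naive_subgraph_oracle(self, rng):
        w = random_connected_graph(rng, 8, weighted=True)
        assert local_efficiency(w, True) == \
            pytest.approx(brute_local_efficiency(w, True), abs=1e-10)


class TestModularity:
    def test_two_triangles_exact_partition(self):
        m = np.zeros((6, 6))
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    if i != j:
                        m[i, j] = 1.0
        part = modularity(m, seed=0, n_restarts=20)
        q_max, best = brute_max_modularity(m)
        assert part.q == pytest.approx(0.5, abs=1e-12)
        assert part.q == pytest.approx(q_max, abs=1e-12)
        assert len(np.unique(part.membership[:3])) == 1
        assert part.membership[0] != part.membership[3]

    def test_complete_graph_no_structure(self):
        part = modularity(complete_graph(8), seed=0, n_restarts=10)
        assert part.q <= 1e-9

    def test_q_matches_newman_formula_for_partition(self, rng):
        w = random_connected_graph(rng, 8, weighted=True)
        part = modularity(w, seed=1, n_restarts=20)
        blocks = part.modules()
        assert part.q == pytest.approx(newman_modularity(w, blocks), abs=1e-10)

    def test_planted_two_block_recovery(self, rng):
        n = 32
        blocks = [list(range(16)), list(range(16, 32))]
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                same = (i < 16) == (j < 16)
                p = 0.9 if same else 0.05
                if rng.random() < p:
                    m[i, j] = m[j, i] = 1.0
        part = modularity(m, seed=0, n_restarts=20)
        for block in blocks:
            assert len(np.unique(part.membership[block])) == 1
        assert part.membership[0] != part.membership[16]

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            modularity(np.zeros((4, 4)))


class TestRandomReference:
    def test_degree_sequence_preserved(self, rng):
        w = random_connected_graph(rng, 16, weighted=True, p_edge=0.3)
        for null in random_reference(w, n_random=5, seed=0):
            assert np.array_equal(degrees(null), degrees(w))

    def test_weight_multiset_preserved(self, rng):
        w = random_connected_graph(rng, 16, weighted=True, p_edge=0.3)
        orig = np.sort(w[np.triu_indices(16, k=1)])
        for null in random_reference(w, n_random=5, seed=0):
            assert np.allclose(np.sort(null[np.triu_indices(16, k=1)]), orig)

    def test_lattice_nulls_lose_clustering(self):
        lattice = ws_matrix(32, 6, 0.0)
        c_lattice = clustering_coefficient(lattice, False)
        nulls = random_reference(lattice, n_random=20, seed=0)
        c_null = np.mean([clustering_coefficient(m, False) for m in nulls])
        assert c_null < 0.5 * c_lattice

    def test_deterministic_given_seed(self, rng):
        w = random_connected_graph(rng, 12, weighted=True)
        a = random_reference(w, n_random=3, seed=7)
        b = random_reference(w, n_random=3, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)


class TestNormalizedMetrics:
    def test_er_graph_near_unity(self, rng):
        # an Erdos-Renyi graph is its own null model up to fluctuations
        g = nx.gnm_random_graph(32, 120, seed=4)
        m = nx.to_numpy_array(g)
        nulls = random_reference(m, n_random=20, seed=0)
        lam, gam, sig = normalized_metrics(m, nulls, weighted=False)
        assert lam == pytest.approx(1.0, abs=0.1)
        assert gam == pytest.approx(1.0, abs=0.5)

    def test_small_world_sigma_exceeds_one(self):
        m = ws_matrix(32, 6, 0.1, seed=1)
        nulls = random_reference(m, n_random=20, seed=0)
        _, _, sig = normalized_metrics(m, nulls, weighted=False)
        assert sig > 1.0

    def test_sigma_identity_exact(self, rng):
        w = random_connected_graph(rng, 10, weighted=True)
        nulls = random_reference(w, n_random=5, seed=3)
        lam, gam, sig = normalized_metrics(w, nulls, weighted=True)
        assert sig == gam / lam  # identical floating-point operation

    def test_relabeling_invariance(self, rng):
        w = random_connected_graph(rng, 9, weighted=True)
        perm = rng.permutation(9)
        wp = w[np.ix_(perm, perm)]
        assert characteristic_path_length(w, True) == \
            pytest.approx(characteristic_path_length(wp, True), abs=1e-12)
        assert clustering_coefficient(w, True) == \
            pytest.approx(clustering_coefficient(wp, True), abs=1e-12)


class TestMetricSetPanel:
    def test_panel_fields_consistent(self, rng):
        w = random_connected_graph(rng, 16, weighted=True, p_edge=0.35)
        ms = compute_metric_set(w, weighted=True, n_random=5, seed=0,
                                n_restarts=10)
        assert ms.sigma == ms.gamma_norm / ms.lambda_norm
        assert 0 <= ms.e_glob <= 1 or ms.e_glob > 0  # weighted can exceed 1
        assert -0.5 <= ms.q <= 1
        assert np.allclose(ms.degree, degrees(w))
        assert np.allclose(ms.strength, strengths(w))

    def test_brute_force_oracle_panel(self, rng):
        w = random_connected_graph(rng, 7, weighted=True)
        assert characteristic_path_length(w, True) == \
            pytest.approx(brute_char_path_length(w, True), abs=1e-10)
        assert global_efficiency(w, True) == \
            pytest.approx(brute_global_efficiency(w, True), abs=1e-10)
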