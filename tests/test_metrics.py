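"""Graph topology metrics, null models, and small-worldness."""

import numpy as np
import pytest

import _oracles as oracle
from impnet.metrics import (
    NullEnsemble,
    betweenness_centrality,
    characteristic_path_length,
    clustering_coefficient,
    degree_centrality,
    generate_matched_nulls,
    global_efficiency,
    identify_hubs,
    local_efficiency,
    normalize_nodal,
    small_worldness,
    weight_to_distance,
)


def complete(n, w=1.0):
    return w * (np.ones((n, n)) - np.eye(n))


def ring_lattice(n, k):
    W = np.zeros((n, n))
    for i in range(n):
        for d in range(1, k // 2 + 1):
            j = (i + d) % n
            W[i, j] = W[j, i] = 1.0
    return W


class TestWeightToDistance:
    def test_reciprocal_and_sentinel(self, path3):
        D = weight_to_distance(2.0 * path3)
        assert D[0, 1] == 0.5
        assert np.isinf(D[0, 2])
        assert np.all(np.diag(D) == 0)

    def test_unit_weights_give_hop_counts(self, path3):
        D = weight_to_distance(path3)
        assert D[0, 1] == 1.0


class TestClustering:
    def test_triangle_is_fully_clustered(self, triangle):
        cp, per_node = clustering_coefficient(triangle)
        assert cp == pytest.approx(1.0)
        np.testing.assert_allclose(per_node, 1.0)

    def test_path_has_no_triangles(self, path3):
        assert clustering_coefficient(path3)[0] == 0.0

    def test_k4_fully_clustered(self):
        assert clustering_coefficient(complete(4))[0] == pytest.approx(1.0)

    def test_ring_lattice_closed_form(self):
        # binary clustering of a K-neighbor ring lattice is 3(K-2)/(4(K-1))
        for n, k in [(30, 6), (90, 8)]:
            cp, _ = clustering_coefficient(ring_lattice(n, k))
            assert cp == pytest.approx(3 * (k - 2) / (4 * (k - 1)), abs=1e-12)

    def test_max_rescaling_keeps_values_in_unit_interval(self, rng):
        W = oracle.random_weighted_graph(rng)
        _, per_node = clustering_coefficient(W)
        assert np.all(per_node >= 0) and np.all(per_node <= 1 + 1e-12)


class TestPathLength:
    def test_path3(self, path3):
        lp, unreachable = characteristic_path_length(path3)
        assert lp == pytest.approx(4 / 3)
        assert unreachable == 0

    def test_complete_graph(self):
        assert characteristic_path_length(complete(5))[0] == pytest.approx(1.0)

    def test_disconnected_components_counted(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        lp, unreachable = characteristic_path_length(W)
        assert lp == pytest.approx(1.0)
        # 12 ordered pairs, 4 reachable within the two dyads
        assert unreachable == 8

    def test_edgeless_graph_raises(self):
        with pytest.raises(ValueError, match="no finite paths"):
            characteristic_path_length(np.zeros((3, 3)))


class TestEfficiency:
    def test_global_complete(self):
        assert global_efficiency(complete(4)) == pytest.approx(1.0)

    def test_global_path3(self, path3):
        assert global_efficiency(path3) == pytest.approx(5 / 6)

    def test_global_edgeless_is_zero(self):
        assert global_efficiency(np.zeros((4, 4))) == 0.0

    def test_local_k4(self):
        el, per_node = local_efficiency(complete(4))
        assert el == pytest.approx(1.0)
        np.testing.assert_allclose(per_node, 1.0)

    def test_local_star_and_path_are_zero(self, path3):
        star = np.zeros((4, 4))
        star[0, 1:] = star[1:, 0] = 1.0
        assert local_efficiency(star)[0] == 0.0
        assert local_efficiency(path3)[0] == 0.0


class TestCentrality:
    def test_degree_star(self):
        star = np.zeros((4, 4))
        star[0, 1:] = star[1:, 0] = 1.0
        np.testing.assert_allclose(degree_centrality(star, "strength"), [3, 1, 1, 1])

    def test_degree_weighted_vs_binary(self, triangle):
        W = 2.0 * triangle
        np.testing.assert_allclose(degree_centrality(W, "strength"), 4.0)
        np.testing.assert_allclose(degree_centrality(W, "binary"), 2.0)

    def test_degree_isolated_node(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        assert degree_centrality(W, "strength")[2] == 0
        assert degree_centrality(W, "binary")[2] == 0

    def test_betweenness_path3(self, path3):
        np.testing.assert_allclose(betweenness_centrality(path3), [0, 1, 0])

    def test_betweenness_complete_graph_is_zero(self):
        np.testing.assert_allclose(betweenness_centrality(complete(5)), 0.0)


class TestOracleEquivalence:
    """Implementation vs naive Floyd-Warshall / path-enumeration references."""

    def test_random_battery(self, rng):
        for _ in range(25):
            W = oracle.random_weighted_graph(rng, n_max=8)
            lp, unreachable = characteristic_path_length(W)
            lp_ref, unreachable_ref = oracle.path_length_mean(W)
            assert lp == pytest.approx(lp_ref, abs=1e-10)
            assert unreachable == unreachable_ref
            assert global_efficiency(W) == pytest.approx(oracle.global_efficiency(W), abs=1e-10)
            np.testing.assert_allclose(
                betweenness_centrality(W), oracle.betweenness(W), atol=1e-10
            )


class TestNormalizationAndHubs:
    def test_mean_division(self):
        np.testing.assert_allclose(normalize_nodal([3, 1, 1, 1]), [2, 2 / 3, 2 / 3, 2 / 3])

    def test_normalized_mean_is_one(self, rng):
        v = rng.uniform(0.1, 10, size=17)
        assert normalize_nodal(v).mean() == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_nodal([0, 0, 0])

    def test_hub_rule_sample_sd(self):
        # mean 1.5, sample sd 1.0 -> threshold 2.5 -> only the 3
        assert identify_hubs([3, 1, 1, 1]) == {0}

    def test_constant_vector_has_no_hubs(self):
        assert identify_hubs([2.0] * 6) == set()

    def test_single_extreme_value(self):
        assert identify_hubs([1, 1, 1, 1, 1, 1, 1, 9]) == {7}


class TestNullEnsemble:
    def make_net(self, rng, n=20, p=0.3):
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    W[i, j] = W[j, i] = rng.uniform(0.5, 4.0)
        return W

    def test_degree_sequence_and_weights_preserved(self, rng):
        W = self.make_net(rng)
        ens = generate_matched_nulls(W, n_nulls=20, seed=5)
        deg = np.count_nonzero(W, axis=1)
        w_sorted = np.sort(W[np.triu_indices_from(W, 1)][W[np.triu_indices_from(W, 1)] > 0])
        for Wn in ens.networks:
            np.testing.assert_array_equal(np.count_nonzero(Wn, axis=1), deg)
            iu = np.triu_indices_from(Wn, 1)
            np.testing.assert_allclose(np.sort(Wn[iu][Wn[iu] > 0]), w_sorted)
            np.testing.assert_array_equal(Wn, Wn.T)
            assert np.all(np.diag(Wn) == 0)

    def test_topology_actually_randomized(self, rng):
        W = self.make_net(rng)
        ens = generate_matched_nulls(W, n_nulls=3, seed=1)
        assert any(np.any((Wn > 0) != (W > 0)) for Wn in ens.networks)

    def test_mean_strength_preserved_in_expectation(self, rng):
        W = self.make_net(rng)
        ens = generate_matched_nulls(W, n_nulls=100, seed=3)
        mean_strength = np.mean([Wn.sum(axis=1).mean() for Wn in ens.networks])
        assert mean_strength == pytest.approx(W.sum(axis=1).mean(), rel=0.05)

    def test_deterministic_given_seed(self, rng):
        W = self.make_net(rng)
        a = generate_matched_nulls(W, n_nulls=5, seed=42)
        b = generate_matched_nulls(W, n_nulls=5, seed=42)
        for Wa, Wb in zip(a.networks, b.networks):
            np.testing.assert_array_equal(Wa, Wb)

    def test_complete_graph_warns_and_keeps_topology(self):
        W = complete(6, 2.0)
        with pytest.warns(UserWarning, match="no legal"):
            ens = generate_matched_nulls(W, n_nulls=2, seed=0)
        for Wn in ens.networks:
            np.testing.assert_array_equal(Wn > 0, W > 0)


class TestSmallWorldness:
    def test_self_ensemble_normalizes_to_one(self, rng):
        W = TestNullEnsemble().make_net(rng)
        ens = NullEnsemble(networks=[W.copy()], generator_seed=0, rewires_per_edge=0)
        gamma, lambda_, sigma = small_worldness(W, ens)
        assert gamma == pytest.approx(1.0)
        assert lambda_ == pytest.approx(1.0)
        assert sigma == pytest.approx(1.0)

    def test_random_graph_self_normalizes_near_one(self, rng):
        # Erdos-Renyi topology: nulls are statistically equivalent
        n = 90
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 8 / (n - 1):
                    W[i, j] = W[j, i] = 1.0
        ens = generate_matched_nulls(W, n_nulls=30, seed=9)
        _, _, sigma = small_worldness(W, ens)
        assert 0.8 <= sigma <= 1.2

    def test_weight_scale_invariance(self, rng):
        """Scaling all weights by c leaves gamma/lambda/sigma unchanged,
        scales Lp by 1/c and E_glob by c, and preserves betweenness order."""
        W = TestNullEnsemble().make_net(rng, n=15, p=0.4)
        c = 3.7
        ens1 = generate_matched_nulls(W, n_nulls=10, seed=2)
        ens2 = generate_matched_nulls(c * W, n_nulls=10, seed=2)
        g1 = small_worldness(W, ens1)
        g2 = small_worldness(c * W, ens2)
        np.testing.assert_allclose(g1, g2, rtol=1e-10)
        assert characteristic_path_length(c * W)[0] == pytest.approx(
            characteristic_path_length(W)[0] / c
        )
        assert global_efficiency(c * W) == pytest.approx(c * global_efficiency(W))
        np.testing.assert_array_equal(
            np.argsort(betweenness_centrality(W)), np.argsort(betweenness_centrality(c * W))
        )
        np.testing.assert_array_equal(
            degree_centrality(W, "binary"), degree_centrality(c * W, "binary")
        )
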