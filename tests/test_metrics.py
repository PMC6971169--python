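"""Graph metrics: closed-form canonical graphs, brute-force oracle
equivalence on random small graphs, rewiring nulls and normalized
small-world indices, and structural invariants."""

import numpy as np
import pytest

from readnet import (
    BinaryNetwork,
    betweenness_centrality,
    characteristic_path_length,
    clustering_coefficient,
    compute_global_metrics,
    compute_nodal_metrics,
    degree_centrality,
    global_efficiency,
    local_efficiency,
    normalized_metrics,
    rewire_degree_preserving,
)
from _oracles import (
    betweenness_oracle,
    clustering_oracle,
    global_efficiency_oracle,
    path_length_oracle,
    random_graph,
)


def _net(adj, sparsity=0.5):
    adj = np.asarray(adj, dtype=np.int8)
    return BinaryNetwork(
        adjacency=adj,
        sparsity=sparsity,
        node_labels=tuple(f"n{i}" for i in range(adj.shape[0])),
    )


def complete(n):
    a = np.ones((n, n), int) - np.eye(n, dtype=int)
    return _net(a)


def star(n):
    a = np.zeros((n, n), int)
    a[0, 1:] = 1
    a[1:, 0] = 1
    return _net(a)


def path(n):
    a = np.zeros((n, n), int)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return _net(a)


def cycle(n):
    a = np.zeros((n, n), int)
    for i in range(n):
        a[i, (i + 1) % n] = a[(i + 1) % n, i] = 1
    return _net(a)


def k4_minus_edge():
    a = np.ones((4, 4), int) - np.eye(4, dtype=int)
    a[2, 3] = a[3, 2] = 0
    return _net(a)


def two_disjoint_edges():
    a = np.zeros((4, 4), int)
    a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
    return _net(a)


def ring_lattice(n, k):
    """Each node tied to its k nearest neighbors (k even)."""
    a = np.zeros((n, n), int)
    for i in range(n):
        for d in range(1, k // 2 + 1):
            j = (i + d) % n
            a[i, j] = a[j, i] = 1
    return _net(a)


class TestCanonicalGraphs:
    def test_clustering_closed_forms(self):
        assert clustering_coefficient(complete(3))[0] == pytest.approx(1.0)
        assert clustering_coefficient(star(5))[0] == pytest.approx(0.0)
        assert clustering_coefficient(k4_minus_edge())[0] == pytest.approx(5 / 6)
        assert clustering_coefficient(complete(4))[0] == pytest.approx(1.0)

    def test_path_length_closed_forms(self):
        lp, frac = characteristic_path_length(complete(5))
        assert lp == pytest.approx(1.0) and frac == 1.0
        lp, _ = characteristic_path_length(path(4))
        assert lp == pytest.approx(10 / 6)  # distances {1,1,1,2,2,3}
        lp, frac = characteristic_path_length(two_disjoint_edges())
        assert lp == pytest.approx(1.0) and frac == pytest.approx(2 / 6)

    def test_fully_disconnected_path_length_flagged_missing(self):
        lp, frac = characteristic_path_length(_net(np.zeros((5, 5), int)))
        assert np.isnan(lp) and frac == 0.0

    def test_global_efficiency_closed_forms(self):
        assert global_efficiency(complete(4)) == pytest.approx(1.0)
        assert global_efficiency(path(3)) == pytest.approx(5 / 6)
        assert global_efficiency(_net(np.zeros((4, 4), int))) == 0.0

    def test_local_efficiency_closed_forms(self):
        assert local_efficiency(complete(3))[0] == pytest.approx(1.0)
        assert local_efficiency(star(5))[0] == pytest.approx(0.0)
        assert local_efficiency(complete(4))[0] == pytest.approx(1.0)

    def test_degree_closed_forms(self):
        assert np.array_equal(degree_centrality(complete(4)), [3, 3, 3, 3])
        assert np.array_equal(degree_centrality(star(5)), [4, 1, 1, 1, 1])
        assert np.array_equal(degree_centrality(_net(np.zeros((3, 3), int))), [0, 0, 0])

    def test_betweenness_closed_forms(self):
        assert np.allclose(betweenness_centrality(path(3)), [0, 1, 0])
        assert np.allclose(betweenness_centrality(star(5)), [6, 0, 0, 0, 0])
        assert np.allclose(betweenness_centrality(cycle(4)), [0.5] * 4)

    def test_normalized_metrics_on_complete_graph_are_unity(self):
        with pytest.warns(UserWarning, match="complete"):
            gamma, lam, sigma = normalized_metrics(complete(6), n_null=3, seed=0)
        assert gamma == lam == sigma == 1.0


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(4))
    def test_random_small_graphs_match_bruteforce(self, trial):
        # 200 random graphs of <= 8 nodes split over parametrized chunks
        rng = np.random.default_rng(100 + trial)
        for _ in range(50):
            n = int(rng.integers(2, 9))
            adj = random_graph(n, float(rng.uniform(0.15, 0.9)), rng)
            lp, frac = characteristic_path_length(adj)
            lp_o, frac_o = path_length_oracle(adj)
            assert frac == pytest.approx(frac_o)
            assert (np.isnan(lp) and np.isnan(lp_o)) or lp == pytest.approx(lp_o)
            assert global_efficiency(adj) == pytest.approx(
                global_efficiency_oracle(adj)
            )
            cp, ci = clustering_coefficient(adj)
            cp_o, ci_o = clustering_oracle(adj)
            assert np.allclose(ci, ci_o) and cp == pytest.approx(cp_o)
            assert np.allclose(
                betweenness_centrality(adj), betweenness_oracle(adj), atol=1e-9
            )

    def test_tree_leaf_betweenness_is_zero(self, rng):
        # random trees: every degree-1 node lies on no interior path
        for _ in range(20):
            n = 8
            a = np.zeros((n, n), int)
            for i in range(1, n):
                j = int(rng.integers(0, i))
                a[i, j] = a[j, i] = 1
            bc = betweenness_centrality(a)
            deg = a.sum(1)
            assert np.all(bc[deg == 1] == 0)


class TestInvariants:
    def _random_net(self, rng, n=25, p=0.2):
        return _net(random_graph(n, p, rng))

    def test_efficiency_at_least_inverse_path_length_when_connected(self, rng):
        # Jensen: mean(1/d) >= 1/mean(d)
        checked = 0
        while checked < 20:
            net = self._random_net(rng, 20, 0.25)
            lp, frac = characteristic_path_length(net)
            if frac < 1.0:
                continue
            assert global_efficiency(net) >= 1 / lp - 1e-12
            checked += 1

    def test_isomorphism_invariance(self, rng):
        net = self._random_net(rng)
        perm = rng.permutation(net.n_nodes)
        permuted = _net(net.adjacency[np.ix_(perm, perm)])
        for f in (
            lambda g: clustering_coefficient(g)[0],
            lambda g: characteristic_path_length(g)[0],
            global_efficiency,
            lambda g: local_efficiency(g)[0],
        ):
            assert f(permuted) == pytest.approx(f(net))

    def test_adding_edge_never_decreases_efficiency_or_degree(self, rng):
        net = self._random_net(rng, 15, 0.2)
        a = np.array(net.adjacency)
        empty = np.argwhere(np.triu(a == 0, 1))
        i, j = empty[rng.integers(len(empty))]
        e0 = global_efficiency(a)
        d0 = degree_centrality(a)
        a[i, j] = a[j, i] = 1
        assert global_efficiency(a) >= e0 - 1e-12
        assert np.all(degree_centrality(a) >= d0)

    def test_degree_sum_equals_twice_edges(self, rng):
        net = self._random_net(rng)
        nodal = compute_nodal_metrics(net)
        assert nodal["degree"].sum() == 2 * net.n_edges

    def test_sigma_is_gamma_over_lambda(self, rng):
        net = self._random_net(rng, 30, 0.25)
        out = compute_global_metrics(net, n_null=5, seed=3)
        assert out["sigma"] == pytest.approx(out["gamma"] / out["lambda"], abs=1e-12)


class TestRewiring:
    def test_degree_sequence_preserved(self, rng):
        net = _net(random_graph(30, 0.2, rng))
        null = rewire_degree_preserving(net, seed=5)
        assert np.array_equal(degree_centrality(null), degree_centrality(net))
        assert null.n_edges == net.n_edges

    def test_same_seed_identical_output(self, rng):
        net = _net(random_graph(30, 0.2, rng))
        a = rewire_degree_preserving(net, seed=9)
        b = rewire_degree_preserving(net, seed=9)
        assert np.array_equal(a.adjacency, b.adjacency)

    def test_rewiring_actually_changes_the_graph(self, rng):
        net = _net(random_graph(40, 0.15, rng))
        null = rewire_degree_preserving(net, seed=1)
        assert not np.array_equal(null.adjacency, net.adjacency)

    def test_complete_graph_returned_unchanged_with_warning(self):
        net = complete(4)
        with pytest.warns(UserWarning, match="no legal swap"):
            null = rewire_degree_preserving(net, seed=0)
        assert np.array_equal(null.adjacency, net.adjacency)

    def test_too_few_edges_rejected(self):
        with pytest.raises(ValueError, match="2 edges"):
            rewire_degree_preserving(path(2), seed=0)


class TestNormalizedMetrics:
    def test_ring_lattice_highly_clustered_vs_nulls(self):
        net = ring_lattice(90, 8)
        gamma, lam, sigma = normalized_metrics(net, n_null=20, seed=7)
        assert gamma > 1.5
        assert sigma == pytest.approx(gamma / lam)

    def test_random_graph_self_similar_under_rewiring(self, rng):
        net = _net(random_graph(90, 0.1, rng))
        gamma, lam, _ = normalized_metrics(net, n_null=20, seed=8)
        assert 0.8 < gamma < 1.2
        assert 0.9 < lam < 1.1

    def test_null_count_validated(self):
        with pytest.raises(ValueError, match="n_null"):
            normalized_metrics(cycle(6), n_null=0)


def test_metric_ranges_on_random_networks(rng):
    # Cp, E_glob, E_loc live in [0,1]; Lp >= 1 whenever any edge exists
    for _ in range(20):
        adj = random_graph(30, float(rng.uniform(0.05, 0.6)), rng)
        cp, _ = clustering_coefficient(adj)
        lp, frac = characteristic_path_length(adj)
        eg = global_efficiency(adj)
        el, _ = local_efficiency(adj)
        assert 0 <= cp <= 1 and 0 <= eg <= 1 and 0 <= el <= 1
        assert 0 <= frac <= 1
        if adj.sum() > 0:
            assert lp >= 1
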