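from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from troopnet.data_model import SocialNetwork, symmetrise
from troopnet.metrics import (
    binary_degrees,
    degree_centralization,
    density,
    generalized_degree,
    global_metrics,
    mean_clustering,
    node_metrics,
    strengths,
    weighted_betweenness,
    weighted_local_clustering,
)

from _oracles import brute_force_betweenness
from conftest import network_from_edges, random_network


def star(n=4):
    return network_from_edges({("C", f"L{i}"): 1.0 for i in range(1, n)})


def triangle(w=1.0):
    return network_from_edges({("A", "B"): w, ("B", "C"): w, ("C", "A"): w})


class TestBinaryDegrees:
    def test_star_centre(self):
        deg = binary_degrees(star())
        assert deg.loc["C", "out_degree"] == 3
        assert deg.loc["C", "in_degree"] == 0
        assert deg.loc["C", "degree"] == 3

    def test_reciprocal_tie_collapses(self):
        net = network_from_edges({("A", "B"): 1.0, ("B", "A"): 2.0})
        deg = binary_degrees(net)
        assert deg.loc["A", "degree"] == 1
        assert deg.loc["B", "degree"] == 1

    def test_empty_network_all_zero(self):
        net = network_from_edges({}, nodes=["A", "B", "C"])
        assert (binary_degrees(net) == 0).all().all()


class TestStrengths:
    def test_out_strength_sums_weights(self):
        net = network_from_edges({("A", "B"): 2.0, ("A", "C"): 3.0})
        assert strengths(net).loc["A", "out_strength"] == pytest.approx(5.0)

    def test_isolated_node_zero(self):
        net = network_from_edges({("A", "B"): 2.0}, nodes=["A", "B", "Z"])
        assert strengths(net).loc["Z", "in_strength"] == 0.0

    def test_conservation(self):
        net = random_network(10, 0.3, np.random.default_rng(4))
        st_ = strengths(net)
        assert st_["in_strength"].sum() == pytest.approx(net.total_weight())
        assert st_["out_strength"].sum() == pytest.approx(net.total_weight())


class TestGeneralizedDegree:
    def test_closed_form(self):
        # k=4, s=9, alpha=.5 -> sqrt(36) = 6
        net = network_from_edges({("A", x): w for x, w in
                                  [("B", 1.0), ("C", 2.0), ("D", 2.0), ("E", 4.0)]})
        val = generalized_degree(net, alpha=0.5, direction="out")
        assert val["A"] == pytest.approx(6.0)

    @given(st.integers(0, 1000), st.floats(0, 1))
    @settings(max_examples=15)
    def test_limits_match_degree_and_strength(self, seed, p_unused):
        net = random_network(8, 0.35, np.random.default_rng(seed))
        for direction in ("in", "out", "all"):
            g0 = generalized_degree(net, 0.0, direction)
            g1 = generalized_degree(net, 1.0, direction)
            deg = binary_degrees(net)
            stg = strengths(net)
            k = deg["degree"] if direction == "all" else deg[f"{direction}_degree"]
            s = (stg["in_strength"] + stg["out_strength"]) if direction == "all" \
                else stg[f"{direction}_strength"]
            np.testing.assert_allclose(g0.to_numpy(), k.to_numpy(dtype=float))
            # strength limit holds wherever a tie exists (isolates stay 0)
            np.testing.assert_allclose(g1.to_numpy(), np.where(k > 0, s, 0.0))

    def test_rejects_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            generalized_degree(triangle(), 1.5)


class TestWeightedBetweenness:
    def test_path_midpoint(self):
        net = network_from_edges({("A", "B"): 1.0, ("B", "A"): 1.0,
                                  ("B", "C"): 1.0, ("C", "B"): 1.0})
        btw = weighted_betweenness(net)
        assert btw["B"] == pytest.approx(2.0)  # A->C and C->A
        assert btw["A"] == btw["C"] == 0.0

    def test_complete_graph_zero(self):
        nodes = ["A", "B", "C", "D"]
        edges = {(u, v): 2.0 for u in nodes for v in nodes if u != v}
        assert weighted_betweenness(network_from_edges(edges)).max() == 0.0

    def test_rejects_nonpositive_weight(self):
        net = network_from_edges({("A", "B"): 0.0})
        with pytest.raises(ValueError, match="weight"):
            weighted_betweenness(net)

    def test_equal_weights_match_unweighted_brandes(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            net = random_network(8, 0.3, rng)
            for u, v in net.graph.edges:
                net.graph[u][v]["weight"] = 3.0  # equal weights: same path sets
            ours = weighted_betweenness(net, alpha=0.5)
            ref = nx.betweenness_centrality(net.graph, normalized=False)
            for v in net.nodes:
                assert ours[v] == pytest.approx(ref[v]), v

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_digraphs(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(int(rng.integers(4, 8)), 0.45, rng)
        ours = weighted_betweenness(net, alpha=0.5)
        oracle = brute_force_betweenness(net, alpha=0.5)
        for v in net.nodes:
            assert ours[v] == pytest.approx(oracle[v], abs=1e-8), v

    def test_tied_paths_split_counts(self):
        # two equal-cost routes A->C: via B1 and via B2
        net = network_from_edges({("A", "B1"): 1.0, ("B1", "C"): 1.0,
                                  ("A", "B2"): 1.0, ("B2", "C"): 1.0})
        btw = weighted_betweenness(net)
        assert btw["B1"] == pytest.approx(0.5)
        assert btw["B2"] == pytest.approx(0.5)

    def test_alpha_zero_ignores_weights(self):
        net = network_from_edges({("A", "B"): 0.001, ("B", "C"): 1000.0,
                                  ("A", "C"): 5.0})
        btw = weighted_betweenness(net, alpha=0.0)
        # with alpha=0 every edge has cost 1; direct A->C is shortest
        assert btw["B"] == 0.0


class TestClustering:
    def test_triangle_fully_clustered(self):
        edges = {("A", "B"): 2.0, ("B", "A"): 2.0, ("B", "C"): 2.0,
                 ("C", "B"): 2.0, ("A", "C"): 2.0, ("C", "A"): 2.0}
        clu = weighted_local_clustering(network_from_edges(edges))
        assert (clu == 1.0).all()

    def test_star_centre_zero_leaves_undefined(self):
        clu = weighted_local_clustering(star())
        assert clu["C"] == 0.0
        assert clu.drop("C").isna().all()

    def test_hand_enumerated_triplets(self):
        # i's neighbours: j (w=2), k (w=2), l (w=4); only j-k closed.
        # triplet values (arith mean): (j,k)=2 closed, (j,l)=3, (k,l)=3 open
        # C(i) = 2 / (2+3+3) = 0.25
        edges = {("I", "J"): 2.0, ("I", "K"): 2.0, ("I", "L"): 4.0, ("J", "K"): 1.0}
        clu = weighted_local_clustering(network_from_edges(edges))
        assert clu["I"] == pytest.approx(0.25)

    def test_geometric_mean_triplet_value(self):
        edges = {("I", "J"): 1.0, ("I", "K"): 4.0, ("I", "L"): 4.0, ("J", "K"): 1.0}
        # gm: closed (J,K)=2, open (J,L)=2, (K,L)=4 -> 2/8
        clu = weighted_local_clustering(network_from_edges(edges), "geometric_mean")
        assert clu["I"] == pytest.approx(0.25)

    def test_unknown_triplet_value_rejected(self):
        with pytest.raises(ValueError, match="triplet_value"):
            weighted_local_clustering(triangle(), "harmonic")

    def test_mean_clustering_excludes_undefined(self):
        assert mean_clustering(star()) == pytest.approx(0.0)  # centre only

    def test_mean_clustering_two_triangles(self):
        edges = {}
        for a, b in [("A", "B"), ("B", "C"), ("C", "A"),
                     ("X", "Y"), ("Y", "Z"), ("Z", "X")]:
            edges[(a, b)] = 1.0
        assert mean_clustering(network_from_edges(edges)) == pytest.approx(1.0)

    def test_no_defined_nodes_flagged_nan(self):
        net = network_from_edges({("A", "B"): 1.0})
        assert math.isnan(mean_clustering(net))


class TestDensityCentralization:
    def test_complete_directed_density_one(self):
        nodes = ["A", "B", "C"]
        edges = {(u, v): 1.0 for u in nodes for v in nodes if u != v}
        assert density(network_from_edges(edges)) == pytest.approx(1.0)

    def test_three_out_edges_of_four_nodes(self):
        net = network_from_edges({("A", "B"): 1, ("A", "C"): 1, ("A", "D"): 1})
        assert density(net) == pytest.approx(0.25)

    def test_empty_density_zero(self):
        assert density(network_from_edges({}, nodes=list("ABCD"))) == 0.0

    def test_density_rejects_single_node(self):
        with pytest.raises(ValueError):
            density(network_from_edges({}, nodes=["A"]))

    @pytest.mark.parametrize("n", [3, 5, 9])
    def test_star_centralization_is_one(self, n):
        assert degree_centralization(star(n)) == pytest.approx(1.0)

    def test_ring_centralization_zero(self):
        nodes = [f"N{i}" for i in range(6)]
        edges = {(nodes[i], nodes[(i + 1) % 6]): 1.0 for i in range(6)}
        assert degree_centralization(network_from_edges(edges)) == pytest.approx(0.0)

    def test_freeman_formula_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            net = random_network(7, 0.4, rng)
            sym = symmetrise(net)
            degs = np.array([sym.graph.degree(v) for v in sym.graph.nodes])
            n = len(degs)
            expected = (degs.max() - degs).sum() / ((n - 1) * (n - 2))
            assert degree_centralization(net) == pytest.approx(expected)

    def test_centralization_rejects_below_three(self):
        with pytest.raises(ValueError):
            degree_centralization(network_from_edges({("A", "B"): 1.0}))


class TestAggregates:
    def test_triangle_globals(self):
        nodes = ["A", "B", "C"]
        edges = {(u, v): 1.0 for u in nodes for v in nodes if u != v}
        gm = global_metrics(network_from_edges(edges))
        assert gm.density == pytest.approx(1.0)
        assert gm.degree_centralization == pytest.approx(0.0)
        assert gm.mean_clustering == pytest.approx(1.0)

    def test_empty_five_node_network(self):
        net = network_from_edges({}, nodes=list("ABCDE"))
        gm = global_metrics(net)
        assert gm.density == 0.0
        assert math.isnan(gm.mean_clustering)
        table = node_metrics(net)
        assert (table[["in_strength", "out_strength"]] == 0).all().all()

    def test_deterministic(self, troop_networks):
        net = troop_networks["grooming"]
        a = node_metrics(net)
        b = node_metrics(net)
        assert a.equals(b)
        assert global_metrics(net) == global_metrics(net)

    def test_global_metrics_agree_with_components(self, troop_networks):
        net = troop_networks["aggression"]
        gm = global_metrics(net)
        assert gm.density == pytest.approx(density(net))
        assert gm.degree_centralization == pytest.approx(degree_centralization(net))
        assert gm.mean_clustering == pytest.approx(mean_clustering(net))


class TestInvariances:
    @pytest.mark.parametrize("seed", range(5))
    def test_relabelling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(8, 0.4, rng)
        names = net.nodes
        perm = list(rng.permutation(names))
        mapping = dict(zip(names, perm))
        g2 = nx.relabel_nodes(net.graph, mapping)
        net2 = SocialNetwork(g2)
        tbl1 = node_metrics(net)
        tbl2 = node_metrics(net2)
        for v in names:
            a = tbl1.loc[v].to_numpy(dtype=float)
            b = tbl2.loc[mapping[v]].to_numpy(dtype=float)
            np.testing.assert_allclose(a, b, equal_nan=True, atol=1e-9)
        assert global_metrics(net) == global_metrics(net2)

    @pytest.mark.parametrize("seed", range(5))
    def test_metric_ranges(self, seed):
        net = random_network(9, 0.35, np.random.default_rng(100 + seed))
        assert 0.0 <= density(net) <= 1.0
        assert 0.0 <= degree_centralization(net) <= 1.0
        clu = weighted_local_clustering(net).dropna()
        assert ((clu >= 0) & (clu <= 1)).all()
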