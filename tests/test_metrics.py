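import math

import networkx as nx
import numpy as np
import pytest

from conftest import make_net, random_weighted_net
from odnet.metrics import (
    compute_all,
    naive_betweenness,
    naive_clustering,
    strength,
    weighted_betweenness,
    weighted_clustering,
)


class TestStrength:
    def test_triangle_forced_arithmetic(self, triangle):
        assert strength(triangle) == {1: 3.0, 2: 4.0, 3: 5.0}

    def test_isolated_node_has_zero_strength(self):
        net = make_net([], nodes=[5])
        assert strength(net) == {5: 0.0}

    def test_sum_of_strengths_is_twice_total_weight(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            net = random_weighted_net(rng)
            total_w = sum(w for *_, w in net.edges())
            assert sum(strength(net).values()) == pytest.approx(2 * total_w)


class TestWeightedBetweenness:
    def test_path_graph_middle_node_is_maximal(self, path3):
        bc = weighted_betweenness(path3)
        assert bc == {1: 0.0, 2: pytest.approx(1.0), 3: 0.0}

    def test_complete_graph_equal_weights_all_zero(self):
        net = make_net([(i, j, 4) for i in range(1, 5) for j in range(i + 1, 5)])
        assert all(v == 0.0 for v in weighted_betweenness(net).values())

    def test_heavy_two_hop_route_undercuts_light_direct_edge(self):
        # direct 1-2 edge costs 1; the 1-5-2 detour costs 1/10 + 1/10
        net = make_net(
            [(1, 2, 1), (1, 5, 10), (5, 2, 10), (2, 3, 10), (3, 4, 1), (4, 1, 1)]
        )
        fast = weighted_betweenness(net)
        slow = naive_betweenness(net)
        for node in fast:
            assert fast[node] == pytest.approx(slow[node], abs=1e-9)
        assert fast[5] > 0.0  # the detour hub carries shortest paths

    def test_unit_cost_option_ignores_weights(self):
        net = make_net([(1, 2, 1), (2, 3, 999), (1, 3, 1)])
        bc = weighted_betweenness(net, cost="unit")
        assert all(v == 0.0 for v in bc.values())  # triangle: no interior nodes

    def test_non_positive_weight_is_fatal(self):
        net = make_net([(1, 2, 0)])
        with pytest.raises(ValueError):
            weighted_betweenness(net)

    def test_disconnected_pairs_contribute_nothing(self):
        net = make_net([(1, 2, 1), (2, 3, 1), (4, 5, 1)])
        bc = weighted_betweenness(net)
        # N = 5 in the normalizer; only the (1,3) pairs cross node 2
        assert bc[2] == pytest.approx(2 / (4 * 3))
        assert bc[4] == 0.0 and bc[5] == 0.0

    def test_matches_networkx_weighted_betweenness(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            net = random_weighted_net(rng, n_max=8)
            g = net.graph.copy()
            for u, v in g.edges:
                g[u][v]["cost"] = 1.0 / g[u][v]["weight"]
            ref = nx.betweenness_centrality(g, weight="cost", normalized=True)
            ours = weighted_betweenness(net)
            for node in ref:
                assert ours[node] == pytest.approx(ref[node], abs=1e-9)


class TestWeightedClustering:
    def test_triangle_is_fully_clustered_whatever_the_weights(self, triangle):
        assert weighted_clustering(triangle) == {1: 1.0, 2: 1.0, 3: 1.0}

    def test_star_has_no_triangles(self):
        net = make_net([(1, k, 2) for k in range(2, 6)])
        assert all(v == 0.0 for v in weighted_clustering(net).values())

    def test_two_triangles_sharing_an_edge_match_enumeration(self):
        net = make_net(
            [(1, 2, 3), (2, 3, 1), (1, 3, 5), (2, 4, 2), (3, 4, 7), (4, 5, 1)]
        )
        fast = weighted_clustering(net)
        slow = naive_clustering(net)
        for node in fast:
            assert fast[node] == pytest.approx(slow[node], abs=1e-12)

    def test_matches_igraph_barrat_transitivity(self):
        igraph = pytest.importorskip("igraph")
        rng = np.random.default_rng(3)
        for _ in range(10):
            net = random_weighted_net(rng, n_max=8)
            nodes = sorted(net.graph.nodes)
            index = {z: i for i, z in enumerate(nodes)}
            edges = [(index[i], index[j]) for i, j, _ in net.edges()]
            weights = [w for *_, w in net.edges()]
            g = igraph.Graph(n=len(nodes), edges=edges)
            ref = g.transitivity_local_undirected(mode="zero", weights=weights)
            ours = weighted_clustering(net)
            for z, r in zip(nodes, ref):
                assert ours[z] == pytest.approx(r, abs=1e-9)

    def test_printed_variant_differs_and_can_exceed_one(self):
        # heavy opposite edge: (w_ij + w_jh)/2 credits weight i never touches
        net = make_net([(1, 2, 1), (1, 3, 1), (2, 3, 100)])
        printed = weighted_clustering(net, variant="printed")
        assert printed[1] > 1.0
        assert weighted_clustering(net)[1] == 1.0


class TestReductionsAndInvariances:
    def test_equal_weights_reduce_to_unweighted_metrics(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            net = random_weighted_net(rng, n_max=7)
            for u, v in net.graph.edges:
                net.graph[u][v]["weight"] = 5
            bc_ref = nx.betweenness_centrality(net.graph, normalized=True)
            c_ref = nx.clustering(net.graph)
            bc = weighted_betweenness(net)
            c = weighted_clustering(net)
            for node in bc_ref:
                assert bc[node] == pytest.approx(bc_ref[node], abs=1e-9)
                assert c[node] == pytest.approx(c_ref[node], abs=1e-9)

    def test_metrics_invariant_under_weight_rescaling(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            net = random_weighted_net(rng)
            bc0, c0 = weighted_betweenness(net), weighted_clustering(net)
            for u, v in net.graph.edges:
                net.graph[u][v]["weight"] *= 7.25
            bc1, c1 = weighted_betweenness(net), weighted_clustering(net)
            for node in bc0:
                assert bc1[node] == pytest.approx(bc0[node], abs=1e-9)
                assert c1[node] == pytest.approx(c0[node], abs=1e-9)

    def test_values_bounded_in_unit_interval(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            net = random_weighted_net(rng, n_max=9)
            for v in weighted_betweenness(net).values():
                assert 0.0 <= v <= 1.0 + 1e-12
            for v in weighted_clustering(net).values():
                assert 0.0 <= v <= 1.0 + 1e-12


class TestComputeAll:
    def test_empty_network_yields_empty_table(self):
        assert compute_all(make_net([])).empty

    def test_rows_agree_with_single_metric_operations(self, triangle):
        table = compute_all(triangle)
        assert list(table["area"]) == [1, 2, 3]
        s, bc, c = strength(triangle), weighted_betweenness(triangle), weighted_clustering(triangle)
        for _, row in table.iterrows():
            a = row["area"]
            assert row["s"] == s[a] and row["BC"] == bc[a] and row["C"] == c[a]
            assert row["k"] == 2

    def test_random_networks_agree_with_oracles(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            net = random_weighted_net(rng, n_max=8)
            table = compute_all(net).set_index("area")
            nb, ncl = naive_betweenness(net), naive_clustering(net)
            for a in table.index:
                assert table.loc[a, "BC"] == pytest.approx(nb[a], abs=1e-9)
                assert table.loc[a, "C"] == pytest.approx(ncl[a], abs=1e-9)
            assert table["s"].sum() == pytest.approx(
                2 * sum(w for *_, w in net.edges())
            )

    def test_degree_zero_implies_zero_strength_and_clustering(self):
        net = make_net([(1, 2, 3)], nodes=[9])
        table = compute_all(net).set_index("area")
        assert table.loc[9, "s"] == 0.0
        assert table.loc[9, "k"] == 0
        assert table.loc[9, "C"] == 0.0
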