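import networkx as nx
import numpy as np
import pytest

from sepsisnet import (
    clustering,
    compute_topology_report,
    find_hubs,
    global_metrics,
    modularity,
    node_centralities,
    topological_coefficient,
)
from sepsisnet.topology import modularity_q

from oracles import (
    oracle_centralities,
    oracle_clustering,
    oracle_newman_q,
    oracle_path_metrics,
    oracle_topological_coefficient,
    random_test_graph,
)


class TestClustering:
    def test_triangle_all_one(self):
        g = nx.complete_graph(3)
        per_node, avg = clustering(g)
        assert all(v == 1.0 for v in per_node.values())
        assert avg == 1.0

    def test_path_no_triangles(self, path3):
        per_node, avg = clustering(path3)
        assert all(v == 0.0 for v in per_node.values())
        assert avg == 0.0

    def test_low_degree_nodes_excluded_from_average(self):
        # triangle plus pendant: pendant (k=1) excluded by default
        g = nx.complete_graph(3)
        g.add_edge(0, "pendant")
        _, avg = clustering(g)
        # node 0 has k=3 with 1 of 3 neighbor pairs linked
        assert avg == pytest.approx((1 / 3 + 1.0 + 1.0) / 3)
        _, avg_all = clustering(g, include_low_degree=True)
        assert avg_all == pytest.approx((1 / 3 + 1.0 + 1.0 + 0.0) / 4)

    def test_matches_triangle_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            g = nx.gnp_random_graph(30, 0.2, seed=int(rng.integers(2**31)))
            per_node, _ = clustering(g)
            ref = oracle_clustering(g)
            for v in g.nodes:
                assert per_node[v] == pytest.approx(ref[v], abs=1e-12)


class TestGlobalMetrics:
    def test_star_centralization_is_one(self):
        rep = global_metrics(nx.star_graph(9))
        assert rep.network_centralization == pytest.approx(1.0)

    def test_regular_graph_zero_heterogeneity(self):
        rep = global_metrics(nx.cycle_graph(8))
        assert rep.network_heterogeneity == 0.0
        assert rep.network_centralization == pytest.approx(0.0)

    def test_path3_hand_enumeration(self, path3):
        rep = global_metrics(path3)
        assert rep.characteristic_path_length == pytest.approx(4 / 3)
        assert rep.network_diameter == 2
        assert rep.shortest_paths == 6
        assert rep.network_density == pytest.approx(2 / 3)

    def test_complete_graph(self):
        rep = global_metrics(nx.complete_graph(6))
        assert rep.network_density == 1.0
        assert rep.network_diameter == 1

    def test_density_degree_identity(self):
        g = random_test_graph(np.random.default_rng(1))
        rep = global_metrics(g)
        n = rep.n_nodes
        assert rep.network_density == pytest.approx(rep.average_degree / (n - 1), abs=1e-12)

    def test_two_nodes_centralization_missing(self):
        g = nx.path_graph(2)
        assert global_metrics(g).network_centralization is None

    def test_disconnected_pairs_excluded_from_path_metrics(self, two_triangles):
        rep = global_metrics(two_triangles)
        assert rep.connected_components == 2
        assert rep.network_diameter == 1
        assert rep.shortest_paths == 12  # 6 ordered pairs per triangle
        assert rep.characteristic_path_length == 1.0

    def test_heterogeneity_variance_formula_flag(self):
        g = nx.star_graph(4)
        cv = global_metrics(g).network_heterogeneity
        var = global_metrics(g, heterogeneity_formula="variance").network_heterogeneity
        degrees = np.array([4, 1, 1, 1, 1], dtype=float)
        assert cv == pytest.approx(degrees.std() / degrees.mean())
        assert var == pytest.approx(degrees.var() / degrees.mean())


class TestNodeCentralities:
    def test_path3_geodesic_enumeration(self, path3):
        nm = node_centralities(path3)
        assert nm.loc["b", "betweenness"] == pytest.approx(1.0)
        assert nm.loc["b", "stress"] == 1
        assert nm.loc["a", "betweenness"] == 0.0

    def test_star_eccentricities(self):
        g = nx.star_graph(5)  # center 0
        nm = node_centralities(g)
        assert nm.loc[0, "eccentricity"] == 1
        assert (nm.drop(index=0).eccentricity == 2).all()

    def test_matches_geodesic_oracle_on_random_graphs(self):
        rng = np.random.default_rng(21)
        for _ in range(6):
            g = nx.gnp_random_graph(25, 0.25, seed=int(rng.integers(2**31)))
            nm = node_centralities(g)
            ref = oracle_centralities(g)
            ref_tc = oracle_topological_coefficient(g)
            for v in g.nodes:
                assert nm.loc[v, "betweenness"] == pytest.approx(ref["betweenness"][v], abs=1e-9)
                assert nm.loc[v, "stress"] == ref["stress"][v]
                assert nm.loc[v, "closeness"] == pytest.approx(ref["closeness"][v], abs=1e-9)
                assert nm.loc[v, "eccentricity"] == ref["eccentricity"][v]
                assert nm.loc[v, "topological_coefficient"] == pytest.approx(ref_tc[v], abs=1e-9)

    def test_eccentricity_bounded_by_component_diameter(self, two_triangles):
        nm = node_centralities(two_triangles)
        assert (nm.eccentricity <= 1).all()


class TestTopologicalCoefficient:
    def test_square_shares_all_neighbors(self):
        g = nx.cycle_graph(4)  # opposite corners share both neighbors
        tc = topological_coefficient(g)
        # only the opposite corner shares neighbors with node 0: J = 2, k = 2
        assert tc[0] == pytest.approx(1.0)

    def test_no_shared_neighbors_zero(self):
        g = nx.path_graph(2)
        tc = topological_coefficient(g)
        assert tc[0] == 0.0 and tc[1] == 0.0


class TestModularity:
    def test_two_triangles_q_half(self, two_triangles):
        partition, q = modularity(two_triangles)
        assert q == pytest.approx(0.5)
        assert {frozenset(c) for c in partition} == {
            frozenset({"a", "b", "c"}),
            frozenset({"x", "y", "z"}),
        }

    def test_single_clique_one_community_q_zero(self):
        g = nx.complete_graph(5)
        assert modularity_q(g, [set(g.nodes)]) == pytest.approx(0.0)

    def test_q_matches_newman_formula_oracle(self, two_triangles):
        partition, q = modularity(two_triangles)
        assert q == pytest.approx(oracle_newman_q(two_triangles, partition), abs=1e-12)

    def test_planted_four_block_recovery(self):
        # dense 8-node blocks, sparse cross edges; adjusted Rand >= 0.9 over 20 seeds
        from sklearn.metrics import adjusted_rand_score

        scores = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sizes = [8, 8, 8, 8]
            g = nx.stochastic_block_model(
                sizes, np.full((4, 4), 0.05) + np.eye(4) * 0.85, seed=int(rng.integers(2**31))
            )
            truth = sum(([i] * s for i, s in enumerate(sizes)), [])
            partition, _ = modularity(g, seed=seed)
            label = {}
            for ci, comm in enumerate(partition):
                for v in comm:
                    label[v] = ci
            pred = [label[v] for v in range(sum(sizes))]
            scores.append(adjusted_rand_score(truth, pred))
        assert np.mean(scores) >= 0.9

    def test_edgeless_graph_rejected(self):
        g = nx.empty_graph(3)
        with pytest.raises(ValueError):
            modularity(g)

    def test_q_not_below_trivial_partition_on_connected_graphs(self):
        for seed in range(5):
            g = nx.connected_watts_strogatz_graph(30, 4, 0.3, seed=seed)
            _, q = modularity(g)
            assert q >= 0.0


class TestFindHubs:
    def test_star_center_is_hub(self):
        hubs = find_hubs(nx.star_graph(6), top_k=1)
        assert hubs == [("0", 6)]

    def test_degree_tie_broken_lexicographically(self):
        g = nx.Graph([("b", "x"), ("b", "y"), ("a", "x"), ("a", "y")])
        assert find_hubs(g, top_k=2) == [("a", 2), ("b", 2)]

    def test_planted_high_degree_gene_ranked_first(self):
        g = nx.star_graph(10)
        g = nx.relabel_nodes(g, {0: "HUBGENE", **{i: f"G{i}" for i in range(1, 11)}})
        g.add_edge("G1", "G2")
        assert find_hubs(g)[0] == ("HUBGENE", 10)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            find_hubs(nx.Graph())


class TestInvariants:
    def test_metrics_invariant_under_relabeling(self):
        g = random_test_graph(np.random.default_rng(33))
        relabeled = nx.relabel_nodes(g, {v: f"node_{v}" for v in g.nodes})
        a = compute_topology_report(g) if g.number_of_edges() else None
        b = compute_topology_report(relabeled) if relabeled.number_of_edges() else None
        if a is not None:
            da, db = a.to_dict(), b.to_dict()
            for key in da:
                if da[key] is None:
                    assert db[key] is None
                else:
                    assert da[key] == pytest.approx(db[key], abs=1e-9), key

    def test_report_table_has_canonical_row_names(self, two_triangles):
        table = compute_topology_report(two_triangles).to_table()
        assert list(table.index)[:3] == [
            "Clustering coefficient",
            "Network density",
            "Network heterogeneity",
        ]
        assert "Modularity, Mc" in table.index
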