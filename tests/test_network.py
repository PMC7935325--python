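import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sepsisnet import (
    BlockSpec,
    CorrelationMatrix,
    ExpressionMatrix,
    SyntheticConfig,
    build_network,
    export_network,
    generate_dataset,
    import_network,
    spearman_matrix,
)


def matrix_from_rows(rows, n_ctrl=None, index=None):
    values = pd.DataFrame(np.asarray(rows, dtype=float))
    values.index = index or [f"g{i}" for i in range(values.shape[0])]
    n = values.shape[1]
    n_ctrl = n if n_ctrl is None else n_ctrl
    values.columns = [f"s{i}" for i in range(n)]
    group = {f"s{i}": ("control" if i < n_ctrl else "case") for i in range(n)}
    return ExpressionMatrix(values=values, group=group)


class TestSpearmanMatrix:
    def test_monotone_pairs(self):
        m = matrix_from_rows(
            [[1, 2, 3, 4, 5], [10, 20, 30, 40, 50], [5, 4, 3, 2, 1]]
        )
        c = spearman_matrix(m)
        assert c.rho[0, 1] == pytest.approx(1.0)
        assert c.rho[0, 2] == pytest.approx(-1.0)
        assert c.p[0, 1] == 0.0 and c.p[0, 2] == 0.0

    def test_hand_computed_rank_example(self):
        # x=(1,2,3,4) vs y=(2,1,4,3): rho = 0.6, t = 0.6*sqrt(2/0.64),
        # two-sided p from t on 2 df ~= 0.40
        m = matrix_from_rows([[1, 2, 3, 4], [2, 1, 4, 3]])
        c = spearman_matrix(m)
        assert c.rho[0, 1] == pytest.approx(0.6)
        t = 0.6 * np.sqrt(2 / (1 - 0.36))
        expected_p = 2 * stats.t.sf(t, df=2)
        assert c.p[0, 1] == pytest.approx(expected_p, rel=1e-9)
        assert expected_p == pytest.approx(0.40, abs=0.01)

    def test_matches_scipy_spearmanr(self):
        rng = np.random.default_rng(3)
        m = matrix_from_rows(rng.standard_normal((8, 15)))
        c = spearman_matrix(m)
        ref_rho, ref_p = stats.spearmanr(m.values.to_numpy(), axis=1)
        np.testing.assert_allclose(c.rho, ref_rho, atol=1e-12)
        np.testing.assert_allclose(c.p, ref_p, atol=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal((5, 12))
        c1 = spearman_matrix(matrix_from_rows(base))
        c2 = spearman_matrix(matrix_from_rows(np.exp(base)))
        np.testing.assert_allclose(c1.rho, c2.rho, atol=1e-12)

    def test_group_selection(self):
        rng = np.random.default_rng(5)
        m = matrix_from_rows(rng.standard_normal((4, 20)), n_ctrl=10)
        c = spearman_matrix(m, group="control")
        assert c.n_samples == 10

    def test_too_few_samples_rejected(self):
        m = matrix_from_rows([[1, 2, 3], [3, 2, 1]])
        with pytest.raises(ValueError, match=">=4"):
            spearman_matrix(m)

    def test_zero_variance_gene_excluded_with_warning(self, caplog):
        m = matrix_from_rows([[1, 2, 3, 4, 5], [7, 7, 7, 7, 7], [2, 1, 4, 3, 5]])
        with caplog.at_level("WARNING"):
            c = spearman_matrix(m)
        assert np.isnan(c.rho[0, 1]) and np.isnan(c.rho[1, 2])
        net = build_network(c, {}, rho_min=0.1, alpha=1.0)
        assert "g1" not in net.nodes


def corr(gene_ids, rho_pairs, p_pairs, n=20):
    k = len(gene_ids)
    rho = np.eye(k)
    p = np.zeros((k, k))
    for (i, j), r in rho_pairs.items():
        rho[i, j] = rho[j, i] = r
    for (i, j), v in p_pairs.items():
        p[i, j] = p[j, i] = v
    return CorrelationMatrix(gene_ids=list(gene_ids), rho=rho, p=p, n_samples=n)


class TestBuildNetwork:
    def test_inclusive_rho_threshold(self):
        c = corr(["a", "b"], {(0, 1): 0.80}, {(0, 1): 0.01})
        net = build_network(c, {"a": "signaling", "b": "signaling"})
        assert net.has_edge("a", "b")
        assert net.edges["a", "b"]["rho"] == pytest.approx(0.80)

    def test_below_threshold_no_edge(self):
        c = corr(["a", "b"], {(0, 1): 0.79}, {(0, 1): 0.001})
        net = build_network(c, {})
        assert net.number_of_edges() == 0

    def test_negative_correlation_excluded_by_signed_rule(self):
        c = corr(["a", "b"], {(0, 1): -0.95}, {(0, 1): 0.0001})
        assert build_network(c, {}).number_of_edges() == 0
        assert build_network(c, {}, absolute=True).has_edge("a", "b")

    def test_insignificant_edge_excluded(self):
        c = corr(["a", "b"], {(0, 1): 0.9}, {(0, 1): 0.2})
        assert build_network(c, {}).number_of_edges() == 0

    def test_isolated_nodes_dropped(self):
        c = corr(
            ["a", "b", "x"], {(0, 1): 0.9}, {(0, 1): 0.001}
        )
        net = build_network(c, {})
        assert set(net.nodes) == {"a", "b"}

    def test_category_attribute_attached(self):
        c = corr(["a", "b"], {(0, 1): 0.9}, {(0, 1): 0.001})
        net = build_network(c, {"a": "innate immunity"})
        assert net.nodes["a"]["category"] == "innate immunity"
        assert net.nodes["b"]["category"] == "U"

    def test_empty_network_is_valid(self, caplog):
        c = corr(["a", "b"], {}, {(0, 1): 1.0})
        with caplog.at_level("WARNING"):
            net = build_network(c, {})
        assert net.number_of_nodes() == 0

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(6)
        m = matrix_from_rows(rng.standard_normal((15, 10)))
        c = spearman_matrix(m)
        edges_loose = {frozenset(e) for e in build_network(c, {}, rho_min=0.5, alpha=0.5).edges}
        edges_tight = {frozenset(e) for e in build_network(c, {}, rho_min=0.7, alpha=0.5).edges}
        assert edges_tight <= edges_loose

    def test_bad_thresholds_rejected(self):
        c = corr(["a", "b"], {(0, 1): 0.9}, {(0, 1): 0.001})
        with pytest.raises(ValueError):
            build_network(c, {}, rho_min=1.01)
        with pytest.raises(ValueError):
            build_network(c, {}, alpha=0.0)


class TestPlantedBlockRecovery:
    def test_block_edges_recovered_with_few_spurious(self):
        # planted 10-gene block at rho_in=0.9, n=50: most within-block edges
        # recovered, almost no cross edges (averaged over 20 seeds here; the
        # 100-seed version runs in the acceptance suite)
        hit_rates, spurious_rates = [], []
        for seed in range(20):
            cfg = SyntheticConfig(
                n_genes=60,
                n_control=50,
                n_case=50,
                blocks=(BlockSpec(gene_indices=tuple(range(10)), rho_in=0.9),),
                seed=seed,
            )
            m, _, _ = generate_dataset(cfg)
            net = build_network(spearman_matrix(m, group="case"), {})
            block = {f"G{i:04d}" for i in range(10)}
            within = sum(1 for a, b in net.edges if a in block and b in block)
            cross = net.number_of_edges() - within
            hit_rates.append(within / 45)
            spurious_rates.append(cross / (60 * 59 / 2 - 45))
        assert np.mean(hit_rates) >= 0.9
        assert np.mean(spurious_rates) < 0.01


class TestExportImport:
    def test_triangle_round_trip(self, two_triangles, tmp_path):
        nx.set_node_attributes(two_triangles, "innate immunity", "category")
        nx.set_edge_attributes(two_triangles, 0.9, "rho")
        path = tmp_path / "net.graphml"
        export_network(two_triangles, path)
        back = import_network(path)
        assert set(back.edges) == set(two_triangles.edges)
        assert back.nodes["a"]["category"] == "innate immunity"

    def test_tsv_export_writes_edge_and_node_tables(self, two_triangles, tmp_path):
        nx.set_edge_attributes(two_triangles, 0.85, "rho")
        path = tmp_path / "net.tsv"
        export_network(two_triangles, path, fmt="tsv")
        edges = pd.read_csv(path, sep="\t")
        nodes = pd.read_csv(tmp_path / "net.tsv.nodes.tsv", sep="\t")
        assert len(edges) == 6
        assert set(nodes.gene) == set(two_triangles.nodes)

    def test_unknown_format_rejected(self, two_triangles, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(two_triangles, tmp_path / "x", fmt="gexf")

    def test_larger_graph_round_trip_edge_count(self, tmp_path):
        g = nx.gnp_random_graph(100, 0.05, seed=1)
        g = nx.relabel_nodes(g, {v: f"G{v}" for v in g.nodes})
        nx.set_edge_attributes(g, 0.8, "rho")
        export_network(g, tmp_path / "g.graphml")
        assert import_network(tmp_path / "g.graphml").number_of_edges() == g.number_of_edges()
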