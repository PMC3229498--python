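"""Correlation matrices, blocks, networks, connectors, level contrasts."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from riboclass import (
    build_network,
    correlation_matrix,
    find_blocks,
    mean_level_contrast,
)
from riboclass.network import CorrelationGraph, write_graphml, write_sif

from conftest import make_catalog


def expr_frame(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )


def graph_from_edges(edges, nodes=None):
    corr_nodes = sorted(set(nodes or ()) | {n for e in edges for n in e})
    corr = pd.DataFrame(
        np.eye(len(corr_nodes)), index=corr_nodes, columns=corr_nodes
    )
    for u, v in edges:
        corr.loc[u, v] = corr.loc[v, u] = 0.95
    return corr


class TestCorrelationMatrix:
    def test_duplicated_rows_correlate_perfectly(self, rng):
        row = rng.normal(size=8)
        corr, _ = correlation_matrix(expr_frame([row, row]))
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_negated_row_anticorrelates(self, rng):
        row = rng.normal(size=8)
        corr, _ = correlation_matrix(expr_frame([row, -row]))
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_two_pass_covariance_formula(self, rng):
        X = rng.normal(size=(20, 10))
        corr, _ = correlation_matrix(expr_frame(X))
        # independent textbook computation: centered two-pass covariance
        for i in range(20):
            for j in range(20):
                xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
                r = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
                assert abs(corr.iloc[i, j] - r) < 1e-12

    def test_zero_variance_gene_excluded_with_warning(self, rng):
        X = rng.normal(size=(3, 6))
        X[1] = 2.5
        corr, excluded = correlation_matrix(expr_frame(X))
        assert excluded == ["g1"] and list(corr.index) == ["g0", "g2"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(expr_frame(np.ones((4, 2))))

    def test_symmetric_unit_diagonal_bounded(self, rng):
        corr, _ = correlation_matrix(expr_frame(rng.normal(size=(12, 7))))
        v = corr.to_numpy()
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert (np.abs(v) <= 1 + 1e-12).all()


class TestFindBlocks:
    def test_planted_modules_recovered(self, rng):
        # two co-expression modules driven by shared latent factors
        t = rng.normal(size=30)
        u = rng.normal(size=30)
        rows = [t + rng.normal(0, 0.3, 30) for _ in range(5)]
        rows += [u + rng.normal(0, 0.3, 30) for _ in range(4)]
        corr, _ = correlation_matrix(expr_frame(rows))
        blocks = find_blocks(corr, threshold=0.8, mode="on_r")
        assert len(blocks) == 2
        assert blocks[0].members == [f"g{i}" for i in range(5)]
        assert blocks[1].members == [f"g{i}" for i in range(5, 9)]

    def test_threshold_one_keeps_only_collinear(self, rng):
        corr, _ = correlation_matrix(expr_frame(rng.normal(size=(4, 10))))
        corr.loc["g0", "g1"] = corr.loc["g1", "g0"] = 1.0  # exact collinearity
        blocks = find_blocks(corr, threshold=1.0, mode="on_r")
        assert len(blocks) == 1 and blocks[0].members == ["g0", "g1"]

    def test_edges_monotone_in_threshold(self, rng):
        corr, _ = correlation_matrix(expr_frame(rng.normal(size=(15, 8))))
        cat = make_catalog([(f"g{i}", f"F{i}", "cyto") for i in range(15)])
        lo = build_network(corr, cat, threshold=0.3, mode="on_r2")
        hi = build_network(corr, cat, threshold=0.6, mode="on_r2")
        assert set(hi.graph.edges) <= set(lo.graph.edges)


class TestBuildNetwork:
    def test_path_graph_middle_is_connector(self):
        corr = graph_from_edges([("a", "b"), ("b", "c")])
        cat = make_catalog([(n, "F1", "plasto") for n in "abc"])
        cg = build_network(corr, cat, threshold=0.75, mode="on_r2")
        assert cg.connectors == ["b"]

    def test_two_cliques_joined_by_one_node(self):
        edges = [("a", "b"), ("a", "c"), ("b", "c"),
                 ("d", "e"), ("d", "f"), ("e", "f"),
                 ("c", "x"), ("x", "d")]
        corr = graph_from_edges(edges)
        cat = make_catalog([(n, "F1", "plasto") for n in "abcdefx"])
        cg = build_network(corr, cat, threshold=0.75, mode="on_r2")
        assert {"c", "x", "d"} == set(cg.connectors)

    def test_connectors_match_remove_and_count_oracle(self, rng):
        for trial in range(25):
            g = nx.gnp_random_graph(int(rng.integers(5, 31)), 0.15,
                                    seed=int(rng.integers(2**31)))
            nodes = [f"g{i}" for i in g.nodes]
            corr = graph_from_edges(
                [(f"g{u}", f"g{v}") for u, v in g.edges], nodes=nodes
            )
            cat = make_catalog([(n, "F1", "cyto") for n in nodes])
            cg = build_network(corr, cat, threshold=0.75, mode="on_r2")
            # brute force: a non-isolated node is a connector iff its
            # removal increases the component count
            base = nx.number_connected_components(cg.graph)
            expected = sorted(
                n for n in cg.graph.nodes
                if cg.graph.degree(n) > 0
                and nx.number_connected_components(
                    cg.graph.subgraph([m for m in cg.graph if m != n])
                ) > base
            )
            assert cg.connectors == expected

    def test_negative_edges_flagged_under_r2(self, rng):
        row = rng.normal(size=10)
        corr, _ = correlation_matrix(expr_frame([row, -row]))
        cat = make_catalog([("g0", "F1", "cyto"), ("g1", "F2", "cyto")])
        cg = build_network(corr, cat, threshold=0.75, mode="on_r2")
        assert cg.graph.edges["g0", "g1"]["sign"] == -1

    def test_exports_readable(self, tmp_path, rng):
        corr = graph_from_edges([("a", "b")])
        cat = make_catalog([("a", "F1", "plasto", "nuclear"),
                            ("b", "F2", "plasto", "plastidial")])
        cg = build_network(corr, cat)
        write_sif(cg, tmp_path / "net.sif")
        write_graphml(cg, tmp_path / "net.graphml")
        assert "a\tcoexp\tb" in (tmp_path / "net.sif").read_text()
        back = nx.read_graphml(tmp_path / "net.graphml")
        assert back.nodes["b"]["genome"] == "plastidial"


class TestMeanLevelContrast:
    def test_exact_double_ratio(self):
        # every set_a value is exactly twice its set_b counterpart
        expr = expr_frame([[2.0, 4.0, 6.0], [6.0, 12.0, 18.0], [1.0, 2.0, 3.0],
                           [3.0, 6.0, 9.0]])
        out = mean_level_contrast(expr, {"g0", "g1"}, {"g2", "g3"})
        assert out.loc["all", "ratio"] == pytest.approx(2.0)

    def test_equal_sets_ratio_one(self, rng):
        vals = rng.normal(10, 1, size=(1, 5))
        expr = expr_frame(np.vstack([vals, vals]))
        out = mean_level_contrast(expr, {"g0"}, {"g1"})
        assert out.loc["all", "ratio"] == pytest.approx(1.0)

    def test_matches_brute_force_group_means(self, rng):
        expr = expr_frame(rng.normal(5, 1, size=(8, 6)))
        groups = {f"s{j}": ("early" if j < 3 else "late") for j in range(6)}
        a = {f"g{i}" for i in range(4)}
        b = {f"g{i}" for i in range(4, 8)}
        out = mean_level_contrast(expr, a, b, groups)
        for grp, samples in (("early", ["s0", "s1", "s2"]),
                             ("late", ["s3", "s4", "s5"])):
            brute = expr.loc[sorted(a), samples].to_numpy().mean()
            assert out.loc[grp, "mean_a"] == pytest.approx(brute)

    def test_empty_or_overlapping_sets_rejected(self, rng):
        expr = expr_frame(rng.normal(size=(3, 4)))
        with pytest.raises(ValueError):
            mean_level_contrast(expr, set(), {"g1"})
        with pytest.raises(ValueError):
            mean_level_contrast(expr, {"g0"}, {"g0", "g1"})
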