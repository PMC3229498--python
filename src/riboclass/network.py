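"""Pearson co-expression structure: blocks, networks, connector genes.

Correlation matrices over expression profiles; co-regulation blocks as
connected components of the thresholded correlation graph; networks at
r-squared >= 0.75 with articulation-point "connector" genes (the
computational analogue of the genes bridging the nuclear and plastidial
expression clouds); and mean-expression contrasts between gene sets.

The threshold can act on r or on r-squared (``mode``): both usages
occur in the literature for the same figures, so both are first-class.
Under the r-squared mode strongly *anti*-correlated pairs also pass;
such edges are kept but carry their sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .catalog import Catalog

__all__ = [
    "CorrelationGraph",
    "CorrelationBlock",
    "correlation_matrix",
    "find_blocks",
    "build_network",
    "mean_level_contrast",
    "write_sif",
    "write_graphml",
]


@dataclass
class CorrelationBlock:
    """A co-regulation block: one connected component of the thresholded graph."""

    members: list[str]
    min_stat: float  # weakest pairwise statistic among members
    density: float  # fraction of member pairs whose edge passes the threshold


@dataclass
class CorrelationGraph:
    """Thresholded co-expression graph with node annotations."""

    graph: nx.Graph
    threshold: float
    mode: str
    connectors: list[str] = field(default_factory=list)

    def connector_report(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g,
                "degree": self.graph.degree(g),
                **{k: self.graph.nodes[g].get(k, "") for k in ("compartment", "genome")},
            }
            for g in self.connectors
        ]
        return pd.DataFrame(rows)


def correlation_matrix(expr: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation between gene rows of an expression matrix.

    Needs at least 3 samples.  Genes with zero variance cannot be
    correlated; they are excluded and returned as a warning list.
    """
    if expr.shape[1] < 3:
        raise ValueError(f"need at least 3 samples, got {expr.shape[1]}")
    values = expr.to_numpy(dtype=float)
    variances = values.var(axis=1)
    excluded = [g for g, v in zip(expr.index, variances) if v == 0.0]
    kept = expr.index[variances > 0.0]
    corr = np.corrcoef(values[variances > 0.0])
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=kept, columns=kept), excluded


def _passes(r: np.ndarray, threshold: float, mode: str) -> np.ndarray:
    if mode == "on_r":
        return r >= threshold
    if mode == "on_r2":
        return r**2 >= threshold
    raise ValueError(f"unknown threshold mode {mode!r}")


def _threshold_graph(
    corr: pd.DataFrame, threshold: float, mode: str
) -> nx.Graph:
    genes = list(corr.index)
    r = corr.to_numpy()
    g = nx.Graph()
    g.add_nodes_from(genes)
    mask = _passes(r, threshold, mode)
    np.fill_diagonal(mask, False)
    ii, jj = np.nonzero(np.triu(mask, 1))
    for i, j in zip(ii, jj):
        g.add_edge(
            genes[i],
            genes[j],
            r=float(r[i, j]),
            r2=float(r[i, j] ** 2),
            sign=int(np.sign(r[i, j])),
        )
    return g


def find_blocks(
    corr: pd.DataFrame,
    threshold: float,
    mode: str = "on_r",
    min_size: int = 2,
) -> list[CorrelationBlock]:
    """Co-regulation blocks: connected components of the thresholded graph.

    Components smaller than ``min_size`` are dropped from the block
    report (they stay in any graph built at the same threshold).
    Blocks are returned largest first.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    g = _threshold_graph(corr, threshold, mode)
    blocks = []
    for comp in nx.connected_components(g):
        if len(comp) < min_size:
            continue
        members = sorted(comp)
        sub = corr.loc[members, members].to_numpy()
        iu = np.triu_indices(len(members), 1)
        pair_stats = sub[iu] if mode == "on_r" else sub[iu] ** 2
        n_edges = g.subgraph(comp).number_of_edges()
        n_pairs = len(members) * (len(members) - 1) // 2
        blocks.append(
            CorrelationBlock(
                members=members,
                min_stat=float(pair_stats.min()),
                density=n_edges / n_pairs,
            )
        )
    return sorted(blocks, key=lambda b: (-len(b.members), b.members))


def build_network(
    corr: pd.DataFrame,
    catalog: Catalog,
    threshold: float = 0.75,
    mode: str = "on_r2",
) -> CorrelationGraph:
    """Thresholded co-expression graph with connector (articulation) genes.

    Connectors are nodes whose removal increases the number of connected
    components — the genes holding otherwise-separate expression clouds
    together.  Node attributes (compartment, genome) come from the
    catalog, which must cover every gene in the matrix.
    """
    by_id = {r.gene_id: r for r in catalog}
    missing = [g for g in corr.index if g not in by_id]
    if missing:
        raise KeyError(f"catalog lacks annotation for {missing[:5]}")
    g = _threshold_graph(corr, threshold, mode)
    for gene in g.nodes:
        rec = by_id[gene]
        g.nodes[gene]["compartment"] = rec.compartment
        g.nodes[gene]["genome"] = rec.genome
    connectors = sorted(nx.articulation_points(g))
    return CorrelationGraph(
        graph=g, threshold=threshold, mode=mode, connectors=connectors
    )


def mean_level_contrast(
    expr: pd.DataFrame,
    set_a: Iterable[str],
    set_b: Iterable[str],
    sample_groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-group mean +/- SE of two gene sets and their ratio a/b.

    Sets must be disjoint and non-empty.  The ratio's standard error is
    propagated to first order: SE(a/b) = |a/b| sqrt((SEa/a)^2 + (SEb/b)^2).
    With no ``sample_groups``, all samples form one group.
    """
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("both gene sets must be non-empty")
    if a & b:
        raise ValueError(f"gene sets overlap: {sorted(a & b)[:5]}")
    missing = (a | b) - set(expr.index)
    if missing:
        raise KeyError(f"expression matrix lacks genes {sorted(missing)[:5]}")
    if sample_groups is None:
        sample_groups = {s: "all" for s in expr.columns}

    rows = []
    for group in sorted(set(sample_groups.values())):
        samples = [s for s in expr.columns if sample_groups.get(s) == group]
        va = expr.loc[sorted(a), samples].to_numpy().ravel()
        vb = expr.loc[sorted(b), samples].to_numpy().ravel()
        ma, mb = va.mean(), vb.mean()
        sea = va.std(ddof=1) / np.sqrt(va.size) if va.size > 1 else 0.0
        seb = vb.std(ddof=1) / np.sqrt(vb.size) if vb.size > 1 else 0.0
        ratio = ma / mb
        se_ratio = abs(ratio) * np.sqrt(
            (sea / ma) ** 2 + (seb / mb) ** 2
        ) if ma and mb else np.nan
        rows.append(
            {
                "group": group,
                "mean_a": ma, "se_a": sea,
                "mean_b": mb, "se_b": seb,
                "ratio": ratio, "se_ratio": se_ratio,
                "n_cells_a": va.size, "n_cells_b": vb.size,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def write_sif(cg: CorrelationGraph, path) -> None:
    """node <TAB> relation <TAB> node, one edge per line."""
    with open(path, "w") as fh:
        for u, v, data in cg.graph.edges(data=True):
            rel = "coexp" if data["sign"] >= 0 else "anticoexp"
            fh.write(f"{u}\t{rel}\t{v}\n")
        for node in nx.isolates(cg.graph):
            fh.write(f"{node}\n")


def write_graphml(cg: CorrelationGraph, path) -> None:
    nx.write_graphml(cg.graph, str(path))
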