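"""Relate expression classes to protein localization.

Summaries connecting the consensus classes back to the catalog: which
ribosome compartments populate each class (with enrichment against the
catalog background), mean log-ratio heat-map matrices per class (or
class x compartment) and experiment, and the class distribution of
control genes co-clustered with the RP set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import pct, round_half_up
from .catalog import Catalog, compartment_shares
from .cluster import ClassAssignment, classify
from .discretize import TrinaryMatrix

__all__ = [
    "ClassCompositionTable",
    "compose_classes",
    "class_by_experiment_means",
    "control_gene_distribution",
]


@dataclass
class ClassCompositionTable:
    """Per-class compartment composition with catalog background.

    ``table`` has one row per (class, compartment) with count, raw
    share, rounded percent, enrichment ratio versus the background
    share, and a two-sided hypergeometric p-value (an addition beyond
    the raw percentages such summaries usually report).
    """

    table: pd.DataFrame
    background: dict[str, tuple[int, int, float]]

    def percentages(self, label: int) -> dict[str, int]:
        sub = self.table[self.table["class"] == label]
        return dict(zip(sub["compartment"], sub["pct"]))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def compose_classes(assign: ClassAssignment, catalog: Catalog) -> ClassCompositionTable:
    """Compartment counts, within-class percentages and enrichment per class.

    Enrichment ratio = class share / background share, the background
    being the compartment shares of the full catalog.  The p-value is a
    two-sided Fisher exact test of the class x compartment 2x2 table.
    """
    by_id = {r.gene_id: r for r in catalog}
    missing = [g for g in assign.labels if g not in by_id]
    if missing:
        raise KeyError(f"assigned gene {missing[0]!r} is missing from the catalog")
    background = compartment_shares(catalog)
    n_total = len(catalog)

    rows = []
    for label in sorted(set(assign.labels.values())):
        members = assign.genes_in_class(label)
        n_class = len(members)
        comps = pd.Series([by_id[g].compartment for g in members])
        for comp, count in comps.value_counts().items():
            share = count / n_class
            bg_count, _, bg_share = background.get(comp, (0, 0, 0.0))
            table = [
                [count, n_class - count],
                [bg_count - count, n_total - n_class - (bg_count - count)],
            ]
            _, p = stats.fisher_exact(table, alternative="two-sided")
            rows.append(
                {
                    "class": label,
                    "compartment": comp,
                    "count": int(count),
                    "n_class": n_class,
                    "share": share,
                    "pct": round_half_up(pct(count, n_class)),
                    "background_share": bg_share,
                    "enrichment": share / bg_share if bg_share else np.nan,
                    "fisher_p": p,
                }
            )
    return ClassCompositionTable(
        table=pd.DataFrame(rows), background=background
    )


def class_by_experiment_means(
    assign: ClassAssignment,
    ratios: pd.DataFrame,
    catalog: Catalog | None = None,
    group_by: str = "class",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean log-ratio per (group, experiment) cell plus cell gene counts.

    ``group_by`` is ``"class"`` or ``"class_compartment"``; the latter
    needs a catalog for compartments.  Empty cells are missing (NaN),
    never zero.  This is the matrix behind the summary heat map where
    each square is the average ratio of same-located genes in one class.
    """
    if group_by not in {"class", "class_compartment"}:
        raise ValueError("group_by must be 'class' or 'class_compartment'")
    genes = [g for g in assign.labels if g in ratios.index]
    missing = set(assign.labels) - set(genes)
    if missing:
        raise KeyError(f"ratio matrix lacks assigned genes, e.g. {sorted(missing)[:3]}")
    if group_by == "class":
        keys = {g: str(assign.labels[g]) for g in genes}
    else:
        if catalog is None:
            raise ValueError("class_compartment grouping requires a catalog")
        by_id = {r.gene_id: r for r in catalog}
        keys = {g: f"{assign.labels[g]}|{by_id[g].compartment}" for g in genes}

    sub = ratios.loc[genes]
    grouper = pd.Series([keys[g] for g in genes], index=sub.index)
    means = sub.groupby(grouper).mean()
    counts = sub.groupby(grouper).size().to_frame("n_genes")
    return means, counts


def control_gene_distribution(
    controls: TrinaryMatrix,
    rp: TrinaryMatrix,
    k: int,
    n_runs: int = 50,
    seed: int = 0,
) -> tuple[dict[int, int], ClassAssignment]:
    """Class distribution of control genes co-clustered with the RP set.

    The controls are appended to the RP trinary matrix and the full
    consensus classing (invariant split + consensus k-means) is re-run
    with identical parameters and seed; the returned distribution maps
    class -> percentage of controls (half-up, summing to 100 up to
    rounding), computed over the controls only.
    """
    overlap = set(controls.genes) & set(rp.genes)
    if overlap:
        raise ValueError(
            f"control genes overlap the RP set: {sorted(overlap)[:5]}"
        )
    if controls.alpha != rp.alpha:
        raise ValueError("control and RP matrices use different alpha thresholds")
    if list(controls.experiments) != list(rp.experiments):
        raise ValueError("control and RP matrices cover different experiments")
    if not controls.genes:
        return {}, None
    combined = TrinaryMatrix(
        rp.genes + controls.genes,
        list(rp.experiments),
        np.vstack([rp.codes, controls.codes]),
        rp.alpha,
    )
    assign = classify(combined, k=k, n_runs=n_runs, seed=seed)
    labels = [assign.labels[g] for g in controls.genes]
    n = len(labels)
    dist = {
        int(c): round_half_up(pct(labels.count(c), n))
        for c in sorted(set(labels))
    }
    return dist, assign
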