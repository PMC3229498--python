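"""Consensus k-means over trinary gene profiles and experiment clustering.

The classing engine: k-means is repeated many times from random
initializations on the trinary codes, run labels are aligned to the
best-converged run by maximal-agreement matching of the k x k
contingency table, and each gene receives the modal aligned label.  A
per-gene stability (fraction of runs agreeing with the modal label)
quantifies consensus; candidate class counts are compared on mean
stability.

Label 0 is reserved for the invariant genes removed before clustering;
cluster labels run 1..k and are numbered canonically by descending
class size, so two equivalent assignments are literally equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .discretize import TrinaryMatrix, split_invariant

__all__ = [
    "ClassAssignment",
    "ExperimentDendrogram",
    "kmeans_consensus",
    "choose_k",
    "cluster_experiments",
    "classify",
]


@dataclass
class ClassAssignment:
    """Per-gene consensus class label with provenance.

    ``labels`` maps gene -> class in {0..k} (0 = invariant); stability
    is the fraction of aligned runs agreeing with the modal label, by
    construction in (0, 1]; invariant genes get stability 1.0.
    """

    labels: dict[str, int]
    k: int
    n_runs: int
    seed: int
    stability: dict[str, float]
    tie_fraction: float = 0.0
    alpha: float | None = None

    def genes_in_class(self, label: int) -> list[str]:
        return [g for g, c in self.labels.items() if c == label]

    def class_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for c in self.labels.values():
            sizes[c] = sizes.get(c, 0) + 1
        return dict(sorted(sizes.items()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": pd.Series(self.labels),
                "stability": pd.Series(self.stability),
            }
        ).rename_axis("gene_id")

    def write(self, path, sidecar=None) -> None:
        """Two-column table; provenance sidecar as key=value lines."""
        self.to_frame().to_csv(path, sep="\t")
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                for key, val in (
                    ("k", self.k), ("n_runs", self.n_runs),
                    ("seed", self.seed), ("alpha", self.alpha),
                    ("tie_fraction", self.tie_fraction),
                ):
                    fh.write(f"{key}={val}\n")


@dataclass
class ExperimentDendrogram:
    """Average-linkage tree over experiments cut into groups."""

    experiments: list[str]
    linkage: np.ndarray
    groups: dict[int, list[str]]

    def group_of(self) -> dict[str, int]:
        return {e: g for g, members in self.groups.items() for e in members}


def _align_labels(reference: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Relabel ``labels`` to maximize agreement with ``reference``.

    Exact assignment matching on the k x k contingency table.
    """
    contingency = np.zeros((k, k), dtype=np.int64)
    np.add.at(contingency, (labels, reference), 1)
    row, col = linear_sum_assignment(contingency, maximize=True)
    mapping = np.empty(k, dtype=np.int64)
    mapping[row] = col
    return mapping[labels]


def _canonical_relabel(
    labels: np.ndarray, codes: np.ndarray, k: int
) -> np.ndarray:
    """Number classes 1..k by descending size.

    Ties on size are broken by the lexicographic order of the class mean
    profile, which depends only on the partition — never on gene order —
    so relabeling commutes with row permutation.
    """
    order_keys = []
    for c in range(k):
        mask = labels == c
        size = int(mask.sum())
        centroid = tuple(codes[mask].mean(axis=0)) if size else (np.inf,)
        order_keys.append((-size, centroid, c))
    ranked = sorted(range(k), key=lambda c: order_keys[c][:2])
    mapping = np.empty(k, dtype=np.int64)
    for new, old in enumerate(ranked, start=1):
        mapping[old] = new
    return mapping[labels]


def kmeans_consensus(
    tm: TrinaryMatrix,
    k: int,
    n_runs: int = 50,
    seed: int = 0,
    n_init: int = 10,
) -> ClassAssignment:
    """Modal-consensus k-means on the rows of a (variable-gene) trinary matrix.

    Each of ``n_runs`` runs is Euclidean k-means from its own random
    initializations (best of ``n_init`` starts, so each run reports a
    well-converged optimum); run labels are aligned to the reference run
    before voting.  Modal ties break deterministically toward the lower
    aligned label and are counted in ``tie_fraction``.

    Stability separates candidate class counts sharply: when the data
    hold four separable classes, every run at k=4 lands on the same
    partition, while at k=3 two competing merges (and at k=5 many
    splits) trade off, so per-gene consensus drops.
    """
    n = len(tm.genes)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} genes available")
    if n_runs < 1:
        raise ValueError("n_runs must be positive")

    X = tm.codes.astype(float)
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    runs = np.empty((n_runs, n), dtype=np.int64)
    inertia = np.empty(n_runs)
    for r in range(n_runs):
        km = KMeans(
            n_clusters=k, init="random", n_init=n_init,
            random_state=int(run_seeds[r]),
        )
        runs[r] = km.fit_predict(X)
        inertia[r] = km.inertia_
    # Align every run to the best (lowest-inertia) run: a poor local
    # optimum as reference makes the matching ambiguous and can split
    # votes for a whole class across two labels.
    ref = int(inertia.argmin())
    for r in range(n_runs):
        if r != ref:
            runs[r] = _align_labels(runs[ref], runs[r], k)

    votes = np.zeros((n, k), dtype=np.int64)
    for r in range(n_runs):
        np.add.at(votes, (np.arange(n), runs[r]), 1)
    top = votes.max(axis=1)
    modal = votes.argmax(axis=1)  # argmax takes the lowest index on ties
    n_ties = int(((votes == top[:, None]).sum(axis=1) > 1).sum())

    final = _canonical_relabel(modal, X, k)
    stability = top / n_runs
    return ClassAssignment(
        labels=dict(zip(tm.genes, (int(c) for c in final))),
        k=k,
        n_runs=n_runs,
        seed=seed,
        stability=dict(zip(tm.genes, (float(s) for s in stability))),
        tie_fraction=n_ties / n,
        alpha=tm.alpha,
    )


@dataclass
class KSelection:
    """Result of comparing candidate class counts."""

    selected_k: int
    diagnostics: pd.DataFrame  # one row per candidate k
    assignments: dict[int, ClassAssignment] = field(default_factory=dict)


def choose_k(
    tm: TrinaryMatrix,
    k_candidates: tuple[int, ...] = (3, 4, 5),
    n_runs: int = 50,
    seed: int = 0,
    n_init: int = 10,
) -> KSelection:
    """Compare candidate k on mean consensus stability.

    Selects the k with the highest mean per-gene stability (ties go to
    the smaller k).  Class-size balance (coefficient of variation of
    class sizes) is reported alongside as a diagnostic.  The selection
    is reported, never silently applied downstream.
    """
    if len(k_candidates) < 2:
        raise ValueError("need at least two candidate k values")
    rows = []
    assignments: dict[int, ClassAssignment] = {}
    for k in sorted(k_candidates):
        assign = kmeans_consensus(tm, k=k, n_runs=n_runs, seed=seed, n_init=n_init)
        assignments[k] = assign
        stab = np.array(list(assign.stability.values()))
        sizes = np.array(list(assign.class_sizes().values()), dtype=float)
        rows.append(
            {
                "k": k,
                "mean_stability": float(stab.mean()),
                "min_stability": float(stab.min()),
                "size_balance_cv": float(sizes.std() / sizes.mean()),
                "tie_fraction": assign.tie_fraction,
            }
        )
    diag = pd.DataFrame(rows).set_index("k")
    best = diag.index[0]
    for k in diag.index[1:]:
        if diag.loc[k, "mean_stability"] > diag.loc[best, "mean_stability"]:
            best = k
    return KSelection(selected_k=int(best), diagnostics=diag, assignments=assignments)


def cluster_experiments(tm: TrinaryMatrix, n_groups: int) -> ExperimentDendrogram:
    """Average-linkage agglomerative clustering of experiment columns.

    Distance between two experiments is the mean absolute difference of
    their trinary codes across genes (Manhattan / n_genes).
    """
    n_exp = len(tm.experiments)
    if n_groups > n_exp:
        raise ValueError(f"n_groups={n_groups} exceeds {n_exp} experiments")
    cols = tm.codes.T.astype(float)
    dist = pdist(cols, metric="cityblock") / len(tm.genes)
    Z = hierarchy.linkage(dist, method="average")
    flat = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
    groups: dict[int, list[str]] = {}
    for exp, g in zip(tm.experiments, flat):
        groups.setdefault(int(g), []).append(exp)
    return ExperimentDendrogram(
        experiments=list(tm.experiments), linkage=Z, groups=dict(sorted(groups.items()))
    )


def classify(
    tm: TrinaryMatrix,
    k: int,
    n_runs: int = 50,
    seed: int = 0,
    n_init: int = 10,
) -> ClassAssignment:
    """Full classing: split invariant genes (class 0), cluster the rest.

    Convenience wrapper combining :func:`split_invariant` and
    :func:`kmeans_consensus` into one assignment over all genes.
    """
    invariant, variable = split_invariant(tm)
    assign = kmeans_consensus(variable, k=k, n_runs=n_runs, seed=seed, n_init=n_init)
    labels = {g: 0 for g in invariant}
    labels.update(assign.labels)
    stability = {g: 1.0 for g in invariant}
    stability.update(assign.stability)
    # restore catalog/matrix gene order
    labels = {g: labels[g] for g in tm.genes}
    stability = {g: stability[g] for g in tm.genes}
    return ClassAssignment(
        labels=labels, k=k, n_runs=n_runs, seed=seed,
        stability=stability, tie_fraction=assign.tie_fraction, alpha=tm.alpha,
    )
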