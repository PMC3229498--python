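"""Trinary significance coding of (log-ratio, p-value) expression data.

Each gene x experiment cell is reduced to a code in {-1, 0, +1}:
repressed, unchanged, induced — nonzero only where the per-comparison
p-value clears the significance threshold.  Genes whose whole row is
zero ("invariant" genes, class 0) are split off before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TrinaryMatrix:
    """Genes x experiments codes in {-1, 0, +1} at threshold ``alpha``."""

    genes: list[str]
    experiments: list[str]
    codes: np.ndarray  # int8, shape (n_genes, n_experiments)
    alpha: float

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.genes), len(self.experiments)):
            raise ValueError(
                f"code matrix shape {self.codes.shape} does not match "
                f"{len(self.genes)} genes x {len(self.experiments)} experiments"
            )
        if not np.isin(self.codes, (-1, 0, 1)).all():
            raise ValueError("trinary codes must lie in {-1, 0, +1}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.genes, columns=self.experiments)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, alpha: float) -> "TrinaryMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(), alpha)

    def subset_genes(self, gene_ids: list[str]) -> "TrinaryMatrix":
        pos = {g: i for i, g in enumerate(self.genes)}
        rows = [pos[g] for g in gene_ids]
        return TrinaryMatrix(list(gene_ids), list(self.experiments),
                             self.codes[rows], self.alpha)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_trinary(path, alpha: float) -> TrinaryMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return TrinaryMatrix.from_frame(df, alpha)


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Per-test threshold after Bonferroni correction over ``n_tests``.

    The default correction divides by the number of experiments each
    gene is tested in, so a whole gene row keeps family-wise error
    ``alpha``.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


def trinarize(
    ratios: pd.DataFrame,
    pvalues: pd.DataFrame,
    alpha: float,
) -> TrinaryMatrix:
    """Code each cell as sign(ratio) where p < alpha, else 0.

    Ratios are assumed log-scaled.  A ratio of exactly zero with a
    significant p-value codes 0 (its sign is undefined).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if ratios.shape != pvalues.shape:
        raise ValueError(
            f"ratio matrix {ratios.shape} and p-value matrix "
            f"{pvalues.shape} are not congruent"
        )
    if list(ratios.index) != list(pvalues.index) or list(ratios.columns) != list(
        pvalues.columns
    ):
        raise ValueError("ratio and p-value matrices must share gene/experiment ids")
    p = pvalues.to_numpy(dtype=float)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    codes = np.where(p < alpha, np.sign(ratios.to_numpy(dtype=float)), 0.0)
    return TrinaryMatrix(
        list(ratios.index), list(ratios.columns), codes.astype(np.int8), alpha
    )


def split_invariant(tm: TrinaryMatrix) -> tuple[list[str], TrinaryMatrix]:
    """Separate genes with all-zero rows (invariant, class 0) from the rest."""
    zero_rows = (tm.codes == 0).all(axis=1)
    invariant = [g for g, z in zip(tm.genes, zero_rows) if z]
    variable_genes = [g for g, z in zip(tm.genes, zero_rows) if not z]
    variable = TrinaryMatrix(
        variable_genes, list(tm.experiments), tm.codes[~zero_rows], tm.alpha
    )
    return invariant, variable
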