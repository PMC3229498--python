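"""Shared fixtures: small catalogs, planted datasets, fixture builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from riboclass import (
    Catalog,
    GeneRecord,
    SyntheticDesign,
    generate_ratio_dataset,
    trinarize,
)
from riboclass.discretize import bonferroni_alpha, split_invariant


def make_catalog(spec: list[tuple], provenance: str = "test") -> Catalog:
    """Build a catalog from (gene_id, family_id, compartment[, genome]) tuples."""
    records = []
    for row in spec:
        gene_id, family_id, compartment = row[:3]
        genome = row[3] if len(row) > 3 else "nuclear"
        records.append(
            GeneRecord(
                gene_id=gene_id,
                name=gene_id,
                family_id=family_id,
                compartment=compartment,
                genome=genome,
            )
        )
    return Catalog(records, provenance=provenance)


def shares_catalog(n_cyto=221, n_mito=71, n_plasto=77, n_nucleus=13, n_unclear=47):
    """A catalog with prescribed compartment totals (default: 429 genes)."""
    spec = []
    i = 0
    for comp, n in (
        ("cyto", n_cyto),
        ("mito", n_mito),
        ("plasto", n_plasto),
        ("nucleus", n_nucleus),
        ("unclear", n_unclear),
    ):
        for _ in range(n):
            i += 1
            spec.append((f"AT{i:05d}", f"F{i:04d}", comp))
    return make_catalog(spec)


def alternative_fixture(n_focal, n_families, n_with_alt, focal_class=2):
    """Catalog + labels realizing a family-alternative bookkeeping row.

    Distributes ``n_focal`` focal-class genes over ``n_families``
    families (as evenly as possible) and adds one non-focal studied
    gene to the first ``n_with_alt`` families.
    """
    assert n_families <= n_focal and n_with_alt <= n_families
    spec, labels = [], {}
    base, extra = divmod(n_focal, n_families)
    g = 0
    for f in range(n_families):
        fam = f"FAM{f:03d}"
        for _ in range(base + (1 if f < extra else 0)):
            g += 1
            gid = f"G{g:04d}"
            spec.append((gid, fam, "cyto"))
            labels[gid] = focal_class
        if f < n_with_alt:
            g += 1
            gid = f"G{g:04d}"
            spec.append((gid, fam, "cyto"))
            labels[gid] = 1  # any non-focal class
    return make_catalog(spec), labels


@pytest.fixture(scope="session")
def balanced_design():
    """Four planted variable classes of 60 genes plus 47 invariant."""
    return SyntheticDesign(seed=1, class_sizes={0: 47, 1: 60, 2: 60, 3: 60, 4: 60})


@pytest.fixture(scope="session")
def balanced_dataset(balanced_design):
    return generate_ratio_dataset(balanced_design)


@pytest.fixture(scope="session")
def balanced_trinary(balanced_design, balanced_dataset):
    ratios, pvalues, truth, experiments = balanced_dataset
    alpha = bonferroni_alpha(0.05, balanced_design.n_experiments)
    return trinarize(ratios, pvalues, alpha)


@pytest.fixture(scope="session")
def balanced_variable(balanced_trinary):
    _, variable = split_invariant(balanced_trinary)
    return variable


@pytest.fixture
def rng():
    return np.random.default_rng(42)
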