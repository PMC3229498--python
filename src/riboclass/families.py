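"""Family-level "transcriptional alternative" statistics and set algebra.

Each ribosomal protein can be encoded by a small gene family (2-7
paralogs).  A family has a *transcriptional alternative* for a focal
expression class when, besides a member in that class, it also contains
a studied member assigned to any other class — two regulatory routes to
the same protein.  Venn decompositions compare gene sets across
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

from ._util import pct, round_half_up
from .catalog import Catalog, family_index
from .cluster import ClassAssignment

__all__ = ["AlternativeStats", "alternative_stats", "venn"]


@dataclass
class AlternativeStats:
    """Family bookkeeping for one focal expression class.

    ``pct_alternative`` = round(100 x families_with_alternative /
    families_with_class), half-up.
    """

    focal_class: int
    n_genes_in_class: int
    n_families_with_class: int
    n_families_with_alternative: int
    pct_alternative: int

    def __post_init__(self) -> None:
        assert self.n_families_with_alternative <= self.n_families_with_class


def alternative_stats(
    assign: ClassAssignment | Mapping[str, int],
    catalog: Catalog,
    focal_class: int,
    studied: Iterable[str] | None = None,
) -> AlternativeStats:
    """Count families with a focal-class member and those with an alternative.

    ``studied`` restricts the analysis to genes actually measured (those
    with probes on the platform); by default every assigned gene is
    studied.  A family counts toward the alternative when it holds at
    least one studied member outside the focal class (class 0 included).
    Families whose studied members are all focal have no alternative.
    The fraction is under-estimated whenever paralogs lack probes.
    """
    labels = assign.labels if isinstance(assign, ClassAssignment) else dict(assign)
    if focal_class not in set(labels.values()):
        raise ValueError(f"focal class {focal_class} absent from the assignment")
    studied_set = set(studied) if studied is not None else set(labels)
    studied_set &= set(labels)

    families = family_index(catalog)
    focal_genes = {g for g in studied_set if labels[g] == focal_class}

    n_with_class = 0
    n_with_alt = 0
    for members in families.values():
        studied_members = [g for g in members if g in studied_set]
        focal_members = [g for g in studied_members if g in focal_genes]
        if not focal_members:
            continue
        n_with_class += 1
        if any(labels[g] != focal_class for g in studied_members):
            n_with_alt += 1
    return AlternativeStats(
        focal_class=focal_class,
        n_genes_in_class=len(focal_genes),
        n_families_with_class=n_with_class,
        n_families_with_alternative=n_with_alt,
        pct_alternative=round_half_up(pct(n_with_alt, n_with_class))
        if n_with_class
        else 0,
    )


def venn(sets: Mapping[str, Iterable[str]]) -> dict[frozenset, set]:
    """Exact region decomposition of 2 or 3 named sets.

    Returns a map from a frozenset of set names to the members lying in
    exactly those sets (and no others).  Region sizes therefore sum to
    the union size and inclusion-exclusion holds by construction.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn expects 2 or 3 named sets")
    named = {name: set(s) for name, s in sets.items()}
    universe = set().union(*named.values())
    regions: dict[frozenset, set] = {}
    names = list(named)
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(named[n] for n in combo))
            outside = set().union(
                *(named[n] for n in names if n not in combo), set()
            )
            regions[frozenset(combo)] = inside - outside
    return regions


def venn_counts(sets: Mapping[str, Iterable[str]]) -> dict[frozenset, int]:
    """Region cardinalities of :func:`venn`."""
    return {k: len(v) for k, v in venn(sets).items()}


def intersection_size(sets: Mapping[str, Iterable[str]], *names: str) -> int:
    """|A ∩ B ∩ ...| — the plain intersection, not the exclusive region."""
    named = {name: set(s) for name, s in sets.items()}
    return len(set.intersection(*(named[n] for n in names)))
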