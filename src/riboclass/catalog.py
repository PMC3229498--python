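"""Ribosomal-protein (RP) gene catalog: data model, I/O and summary shares.

The catalog is the bookkeeping backbone of the analysis: one row per RP
gene with its family, the ribosome its product serves (cytosolic,
mitochondrial or plastid), the genome that encodes it, a pseudogene flag
and per-platform probe identifiers.  The catalog is an *input* — homology
searches, phylogenetics and localization prediction that would build one
are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._util import pct, round_half_up

#: Ribosome compartment served by the mature protein.
COMPARTMENTS = frozenset({"cyto", "mito", "plasto", "nucleus", "unclear"})
#: Genome of origin of the gene itself.
GENOMES = frozenset({"nuclear", "mitochondrial", "plastidial"})

#: Columns every catalog file must carry.
MANDATORY_COLUMNS = ("gene_id", "family_id", "compartment", "genome")

_PROBE_PREFIX = "probe_"
_TRUE_TOKENS = {"1", "true", "yes", "y"}


@dataclass
class GeneRecord:
    """One RP gene.

    ``compartment`` says which ribosome the protein serves; ``genome``
    says which genome encodes the gene — the two are independent (most
    plastid-ribosome proteins are nuclear-encoded).
    """

    gene_id: str
    name: str = ""
    family_id: str = ""
    compartment: str = "unclear"
    genome: str = "nuclear"
    pseudogene: bool = False
    probe_ids: dict[str, str] = field(default_factory=dict)
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r} for {self.gene_id}; "
                f"expected one of {sorted(COMPARTMENTS)}"
            )
        if self.genome not in GENOMES:
            raise ValueError(
                f"unknown genome {self.genome!r} for {self.gene_id}; "
                f"expected one of {sorted(GENOMES)}"
            )
        if not self.family_id and not self.pseudogene:
            raise ValueError(f"non-pseudogene {self.gene_id} lacks a family_id")


@dataclass
class Catalog:
    """Ordered collection of gene records with unique IDs."""

    records: list[GeneRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.gene_id in seen:
                raise ValueError(f"duplicate gene_id {rec.gene_id!r} in catalog")
            seen.add(rec.gene_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, gene_id: str) -> GeneRecord:
        for rec in self.records:
            if rec.gene_id == gene_id:
                return rec
        raise KeyError(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def subset(self, gene_ids: Iterable[str]) -> "Catalog":
        wanted = set(gene_ids)
        missing = wanted - set(self.gene_ids)
        if missing:
            raise KeyError(f"genes absent from catalog: {sorted(missing)[:5]}")
        return Catalog(
            [r for r in self.records if r.gene_id in wanted],
            provenance=self.provenance,
        )


def load_catalog(path: str | Path) -> Catalog:
    """Read a tab-delimited catalog file.

    The header must name at least ``gene_id``, ``family_id``,
    ``compartment`` and ``genome``.  Columns named ``probe_<platform>``
    are folded into each record's ``probe_ids``; any other extra columns
    are preserved verbatim as annotations.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"catalog file {path} is missing mandatory column {col!r}")
    probe_cols = [c for c in df.columns if c.startswith(_PROBE_PREFIX)]
    known = set(MANDATORY_COLUMNS) | {"name", "pseudogene"} | set(probe_cols)
    extra_cols = [c for c in df.columns if c not in known]

    records = []
    for _, row in df.iterrows():
        probe_ids = {
            c[len(_PROBE_PREFIX):]: row[c] for c in probe_cols if row[c] != ""
        }
        records.append(
            GeneRecord(
                gene_id=row["gene_id"],
                name=row.get("name", ""),
                family_id=row["family_id"],
                compartment=row["compartment"],
                genome=row["genome"],
                pseudogene=str(row.get("pseudogene", "")).strip().lower()
                in _TRUE_TOKENS,
                probe_ids=probe_ids,
                annotations={c: row[c] for c in extra_cols},
            )
        )
    return Catalog(records, provenance=str(path))


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    """Write a catalog in the same tab-delimited dialect ``load_catalog`` reads."""
    platforms = sorted({p for r in catalog for p in r.probe_ids})
    extra = sorted({k for r in catalog for k in r.annotations})
    rows = []
    for r in catalog:
        row = {
            "gene_id": r.gene_id,
            "name": r.name,
            "family_id": r.family_id,
            "compartment": r.compartment,
            "genome": r.genome,
            "pseudogene": "1" if r.pseudogene else "0",
        }
        for p in platforms:
            row[_PROBE_PREFIX + p] = r.probe_ids.get(p, "")
        for k in extra:
            row[k] = r.annotations.get(k, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def compartment_shares(
    catalog: Catalog,
) -> dict[str, tuple[int, int, float]]:
    """Per-compartment ``(count, rounded percent, raw fraction)``.

    Percentages are computed over the *full* catalog (pseudogenes
    included in the denominator) and rounded half-up to integers, the
    granularity at which such shares are conventionally reported.
    """
    if len(catalog) == 0:
        raise ValueError("compartment shares of an empty catalog are undefined")
    n = len(catalog)
    out: dict[str, tuple[int, int, float]] = {}
    for comp in sorted(COMPARTMENTS):
        count = sum(1 for r in catalog if r.compartment == comp)
        if count:
            out[comp] = (count, round_half_up(pct(count, n)), count / n)
    return out


def family_index(catalog: Catalog) -> dict[str, list[str]]:
    """Map family_id -> member gene_ids (catalog order preserved).

    Grouping is by family label only; compartment plays no role.
    Pseudogenes without a family label are omitted.
    """
    idx: dict[str, list[str]] = {}
    for rec in catalog:
        if not rec.family_id:
            continue
        idx.setdefault(rec.family_id, []).append(rec.gene_id)
    return idx
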