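"""Synthetic stress-transcriptome and promoter data with planted structure.

Stands in for the public microarray resources: a two-color-array style
dataset of per-gene, per-experiment log-ratios with dye-swap p-values,
carrying five planted response classes, and promoter sets with a
degenerate motif planted at a position-controlled offset versus
motif-free background.  Everything is a pure function of its design,
seed included.

Planted classes mirror the response archetypes seen in stress compendia
of ribosomal-protein genes:

* class 0 — invariant: null in every experiment;
* class 1 — erratic: responds in a small random subset of experiments
  with random sign;
* class 2 — repressed by carbon/nitrogen-status stress, induced by
  biotic stress (the coherent cytosolic-ribosome signature);
* classes 3 and 4 — both repressed by carbon/nitrogen-status stress but
  told apart by a contrasted abiotic response and opposite-signed
  responses to UV and nitrogen re-supply (the two plastid-ribosome
  signatures).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SyntheticDesign",
    "MotifPlantingDesign",
    "generate_ratio_dataset",
    "generate_promoters",
    "default_experiment_groups",
    "IUPAC_CODES",
]

#: IUPAC nucleotide codes and the bases each matches.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

EXPERIMENT_GROUPS = ("biotic", "abiotic", "weak", "CN_status", "UV", "N_resupply")


def default_experiment_groups(n_experiments: int = 49) -> dict[str, str]:
    """Experiment -> stress-group map for the default 49-experiment design.

    Four main stress groups (biotic, abiotic, weak, carbon/nitrogen
    status) plus the UV and nitrogen-re-supply comparisons that tell the
    two plastid classes apart.  For other sizes the same proportions are
    kept, with at least one experiment per group.
    """
    base = {"biotic": 12, "abiotic": 10, "weak": 10, "CN_status": 12,
            "UV": 2, "N_resupply": 3}
    total = sum(base.values())
    if n_experiments < len(base):
        raise ValueError(f"need at least {len(base)} experiments, got {n_experiments}")
    if n_experiments == total:
        counts = dict(base)
    else:
        counts = {g: max(1, int(round(n_experiments * c / total)))
                  for g, c in base.items()}
        # distribute the rounding remainder over the large groups
        order = sorted(base, key=base.get, reverse=True)
        i = 0
        while sum(counts.values()) < n_experiments:
            counts[order[i % len(order)]] += 1
            i += 1
        while sum(counts.values()) > n_experiments:
            g = order[i % len(order)]
            if counts[g] > 1:
                counts[g] -= 1
            i += 1
    groups: dict[str, str] = {}
    k = 1
    for g in EXPERIMENT_GROUPS:
        for _ in range(counts[g]):
            groups[f"E{k:02d}_{g}"] = g
            k += 1
    return groups


@dataclass
class SyntheticDesign:
    """Design of a planted-class log-ratio dataset.

    ``class_sizes`` defaults to the headline membership of the study
    system (47 invariant / 132 erratic / 68 / 32 / 14 coherent genes
    over 49 stress experiments); ``effect_size`` and ``noise_sd`` give a
    standardized effect of 3.
    """

    n_experiments: int = 49
    class_sizes: dict[int, int] = field(
        default_factory=lambda: {0: 47, 1: 132, 2: 68, 3: 32, 4: 14}
    )
    experiment_groups: dict[str, str] | None = None
    effect_size: float = 1.5
    noise_sd: float = 0.5
    erratic_responses: tuple[int, int] = (2, 4)  # inclusive range per class-1 gene
    seed: int = 0

    def groups(self) -> dict[str, str]:
        if self.experiment_groups is not None:
            if len(self.experiment_groups) != self.n_experiments:
                raise ValueError("experiment_groups must cover every experiment")
            return dict(self.experiment_groups)
        return default_experiment_groups(self.n_experiments)


@dataclass
class MotifPlantingDesign:
    """Design of a promoter set with a motif planted at a controlled offset.

    Positions are measured from the 3' end of the promoter (the base
    just upstream of the translation start is -1); ``position_mean`` is
    the planted hit's start offset, e.g. -70.
    """

    n_promoters: int = 200
    promoter_length: int = 1000
    motif: str = "ARGCCCA"
    plant_fraction: float = 1.0
    position_mean: float = -70.0
    position_sd: float = 25.0
    background_gc: float = 0.36  # typical plant upstream-region GC content
    seed: int = 0


def _class_mean_profile(
    label: int, group_of: np.ndarray, effect: float
) -> np.ndarray:
    """Planted mean log-ratio per experiment for a coherent class."""
    mu = np.zeros(group_of.shape[0])
    if label == 2:
        # repressed under nitrogen starvation, induced by biotic stress
        # and restored (induced) on nitrogen re-supply
        mu[group_of == "CN_status"] = -effect
        mu[group_of == "biotic"] = +effect
        mu[group_of == "N_resupply"] = +effect
    elif label == 3:
        mu[group_of == "CN_status"] = -effect
        mu[group_of == "abiotic"] = +effect
        mu[group_of == "UV"] = -effect
        mu[group_of == "N_resupply"] = +effect
    elif label == 4:
        mu[group_of == "CN_status"] = -effect
        mu[group_of == "abiotic"] = -effect
        mu[group_of == "UV"] = +effect
        mu[group_of == "N_resupply"] = -effect
    return mu


def generate_ratio_dataset(
    design: SyntheticDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.DataFrame]:
    """Generate (log-ratio matrix, p-value matrix, true labels, experiment table).

    Log-ratios are the planted class mean plus Gaussian noise of
    ``noise_sd``; each cell's p-value is the two-sided z-test of that
    ratio against zero at the known noise scale, so null cells carry
    uniform p-values and planted effects carry correspondingly small
    ones — internally consistent with how two-color array pipelines
    publish per-comparison (ratio, p) pairs.
    """
    sizes = {k: v for k, v in design.class_sizes.items() if v}
    if not sizes or sum(sizes.values()) == 0:
        raise ValueError("design contains zero genes")
    bad = set(sizes) - {0, 1, 2, 3, 4}
    if bad:
        raise ValueError(f"unknown class labels in design: {sorted(bad)}")
    groups = design.groups()
    experiments = list(groups)
    group_of = np.array([groups[e] for e in experiments])
    n_exp = len(experiments)

    rng = np.random.default_rng(design.seed)
    gene_ids: list[str] = []
    labels: list[int] = []
    mean_rows: list[np.ndarray] = []
    g = 1
    for label in sorted(sizes):
        for _ in range(sizes[label]):
            gene_ids.append(f"G{g:04d}")
            labels.append(label)
            if label == 0:
                mu = np.zeros(n_exp)
            elif label == 1:
                lo, hi = design.erratic_responses
                k = int(rng.integers(lo, hi + 1))
                idx = rng.choice(n_exp, size=k, replace=False)
                signs = rng.choice([-1.0, 1.0], size=k)
                mu = np.zeros(n_exp)
                mu[idx] = signs * design.effect_size
            else:
                mu = _class_mean_profile(label, group_of, design.effect_size)
            mean_rows.append(mu)
            g += 1

    mean = np.vstack(mean_rows)
    ratios = mean + rng.normal(0.0, design.noise_sd, size=mean.shape)
    z = np.abs(ratios) / design.noise_sd
    pvalues = 2.0 * stats.norm.sf(z)

    ratio_df = pd.DataFrame(ratios, index=gene_ids, columns=experiments)
    pval_df = pd.DataFrame(pvalues, index=gene_ids, columns=experiments)
    label_s = pd.Series(labels, index=gene_ids, name="true_class")
    exp_df = pd.DataFrame(
        {"experiment": experiments, "group": [groups[e] for e in experiments]}
    ).set_index("experiment")
    return ratio_df, pval_df, label_s, exp_df


def _validate_iupac(motif: str) -> str:
    motif = motif.upper()
    bad = [c for c in motif if c not in IUPAC_CODES]
    if bad:
        raise ValueError(f"invalid IUPAC code(s) {bad} in motif {motif!r}")
    if not motif:
        raise ValueError("empty motif")
    return motif


def generate_promoters(
    design: MotifPlantingDesign,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate promoter sequences plus a planting truth table.

    Returns ``(records, truth)`` where records are ``(id, sequence)``
    pairs (write with :func:`write_fasta`) and the truth table records,
    per promoter, whether a motif was deliberately planted and at which
    3'-anchored start offset.  Background is i.i.d. at the design's GC
    content, so the motif may still occur by chance in unplanted
    promoters — the truth table records only deliberate plants.
    """
    motif = _validate_iupac(design.motif)
    L, m = design.promoter_length, len(motif)
    if m > L:
        raise ValueError(f"motif ({m} nt) longer than promoter ({L} nt)")
    if not 0.0 <= design.plant_fraction <= 1.0:
        raise ValueError("plant_fraction must lie in [0, 1]")

    rng = np.random.default_rng(design.seed)
    gc = design.background_gc
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))

    n_plant = int(round(design.plant_fraction * design.n_promoters))
    planted_flags = np.zeros(design.n_promoters, dtype=bool)
    planted_flags[rng.choice(design.n_promoters, size=n_plant, replace=False)] = True

    records: list[tuple[str, str]] = []
    rows = []
    for i in range(design.n_promoters):
        seq = rng.choice(bases, size=L, p=probs)
        offset: float | None = None
        if planted_flags[i]:
            raw = rng.normal(design.position_mean, design.position_sd)
            # clip so the whole motif sits inside the sequence
            offset = int(np.clip(round(raw), -L, -m))
            start = L + offset
            realization = [rng.choice(list(IUPAC_CODES[c])) for c in motif]
            seq[start:start + m] = realization
        pid = f"P{i + 1:04d}"
        records.append((pid, "".join(seq)))
        rows.append({"gene_id": pid, "planted": planted_flags[i],
                     "position": offset if offset is not None else pd.NA})
    truth = pd.DataFrame(rows).set_index("gene_id")
    return records, truth


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write ``(id, sequence)`` pairs as a standard FASTA file."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(s), id=i, description="") for i, s in records],
        str(path),
        "fasta",
    )
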