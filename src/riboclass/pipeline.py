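"""End-to-end orchestration: data -> codes -> classes -> summaries.

A run is described by a :class:`RunConfig` (usually loaded from YAML),
validated up front, and executed stage by stage; every stage writes its
tab-delimited table into the output directory and a manifest records
parameters, seeds and SHA-256 digests of every product, so re-running
the same config reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import class_by_experiment_means, compose_classes
from .catalog import Catalog, GeneRecord, load_catalog, write_catalog
from .cluster import choose_k, classify, cluster_experiments
from .discretize import bonferroni_alpha, split_invariant, trinarize
from .families import alternative_stats
from .motifs import (
    MotifPattern,
    SITE_II,
    TELO_BOX,
    background_envelope,
    class_occupancy,
    envelope_table,
    read_promoters,
    scan,
)
from .network import build_network, correlation_matrix, find_blocks, write_graphml, write_sif
from .synthetic import (
    MotifPlantingDesign,
    SyntheticDesign,
    generate_promoters,
    generate_ratio_dataset,
    write_fasta,
)

log = logging.getLogger("riboclass")

_COMPARTMENT_MIX = {
    # class -> (compartments, probabilities); invariant and erratic
    # classes are mixed with a mitochondrial over-representation, the
    # coherent classes map onto their archetypes
    0: (("cyto", "mito", "plasto", "nucleus", "unclear"), (0.40, 0.34, 0.10, 0.06, 0.10)),
    1: (("cyto", "mito", "plasto", "nucleus", "unclear"), (0.55, 0.30, 0.05, 0.05, 0.05)),
    2: (("cyto",), (1.0,)),
    3: (("plasto",), (1.0,)),
    4: (("plasto",), (1.0,)),
}


def synthetic_catalog(truth: pd.Series, seed: int = 0) -> Catalog:
    """Catalog consistent with planted class labels.

    Compartments follow the class archetypes (class 2 cytosolic, class
    3 plastid/nuclear-encoded, class 4 plastid/plastid-encoded, classes
    0-1 mixed); genes of a compartment are partitioned into families of
    1-4 members so family statistics have real structure.
    """
    rng = np.random.default_rng(seed)
    records: dict[str, GeneRecord] = {}
    comp_of: dict[str, str] = {}
    for gene, label in truth.items():
        comps, probs = _COMPARTMENT_MIX[int(label)]
        comp_of[gene] = str(rng.choice(comps, p=probs))
    by_comp: dict[str, list[str]] = {}
    for gene, comp in comp_of.items():
        by_comp.setdefault(comp, []).append(gene)
    fam_counter = 0
    for comp, genes in by_comp.items():
        genes = list(genes)
        rng.shuffle(genes)
        i = 0
        while i < len(genes):
            size = int(rng.integers(1, 5))
            fam_counter += 1
            for g in genes[i:i + size]:
                records[g] = GeneRecord(
                    gene_id=g,
                    name=g,
                    family_id=f"FAM{fam_counter:03d}",
                    compartment=comp,
                    genome="plastidial"
                    if (comp == "plasto" and truth[g] == 4)
                    else "nuclear",
                    probe_ids={"array": f"probe_{g}"},
                )
            i += size
    ordered = [records[g] for g in truth.index]
    return Catalog(ordered, provenance="synthetic catalog")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; see ``validate`` for the rules."""

    seed: int
    output_dir: str
    alpha: float | None = None  # None -> Bonferroni 0.05 / n_experiments
    k: int | None = None  # None -> select from k_candidates
    k_candidates: tuple[int, ...] = (3, 4, 5)
    n_runs: int = 50
    synthetic: dict | None = None
    inputs: dict = field(default_factory=dict)
    network: dict = field(default_factory=lambda: {"threshold": 0.75, "mode": "on_r2"})
    blocks: dict = field(default_factory=lambda: {"threshold": 0.8, "mode": "on_r"})
    motifs: list[MotifPattern] = field(default_factory=lambda: [SITE_II, TELO_BOX])
    envelope: dict = field(default_factory=lambda: {"n_resamples": 200})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        motifs = [
            MotifPattern(m["name"], m["iupac"], m["center"], m["halfwidth"])
            for m in raw.pop("motifs", [])
        ] or [SITE_II, TELO_BOX]
        kc = tuple(raw.pop("k_candidates", (3, 4, 5)))
        return cls(motifs=motifs, k_candidates=kc, **raw)


def validate_config(config: RunConfig) -> list[str]:
    """All violations at once; an empty list means the config is valid."""
    v: list[str] = []
    if config.seed is None:
        v.append("seed is mandatory")
    if config.alpha is not None and not 0 < config.alpha < 1:
        v.append(f"alpha must lie in (0, 1), got {config.alpha}")
    for k in config.k_candidates:
        if k < 2:
            v.append(f"k candidate {k} invalid: k must be >= 2")
    if config.k is not None and config.k < 2:
        v.append(f"k={config.k} invalid: k must be >= 2")
    if config.n_runs < 1:
        v.append("n_runs must be positive")
    if config.synthetic is None:
        for key in ("catalog", "ratios", "pvalues"):
            path = config.inputs.get(key)
            if path is None:
                v.append(f"inputs.{key} required when no synthetic design is given")
            elif not Path(path).exists():
                v.append(f"inputs.{key} path does not exist: {path}")
        promoters = config.inputs.get("promoters")
        if config.motifs and promoters is None:
            v.append("motif stage enabled but no promoter FASTA configured")
        elif promoters is not None and not Path(promoters).exists():
            v.append(f"inputs.promoters path does not exist: {promoters}")
    mode = config.network.get("mode", "on_r2")
    if mode not in {"on_r", "on_r2"}:
        v.append(f"unknown network threshold mode {mode!r}")
    return v


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest dictionary.

    Stage failure raises with the stage name; outputs written before
    the failure stay on disk and the manifest is not written, so a
    partial run is recognizable by its missing manifest.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {},
        "outputs": {},
        "stages": [],
    }

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path.relative_to(outdir)),
            "sha256": _sha256(path),
        }

    stage = "load"
    try:
        # ------------------------------------------------------ data
        if config.synthetic is not None:
            stage = "simulate"
            syn = dict(config.synthetic)
            promoter_cfg = syn.pop("promoters", {})
            if "class_sizes" in syn:
                syn["class_sizes"] = {int(k): v for k, v in syn["class_sizes"].items()}
            design = SyntheticDesign(seed=config.seed, **syn)
            ratios, pvalues, truth, experiments = generate_ratio_dataset(design)
            catalog = synthetic_catalog(truth, seed=config.seed)
            ratios.to_csv(outdir / "ratios.tsv", sep="\t", index_label="gene_id")
            pvalues.to_csv(outdir / "pvalues.tsv", sep="\t", index_label="gene_id")
            truth.to_frame().to_csv(outdir / "true_classes.tsv", sep="\t")
            write_catalog(catalog, outdir / "catalog.tsv")
            for name in ("ratios", "pvalues", "true_classes", "catalog"):
                emit(name, outdir / f"{name}.tsv")
            promoter_sets = {}
            if promoter_cfg:
                for label, pcfg in promoter_cfg.items():
                    pdesign = MotifPlantingDesign(
                        seed=config.seed + int(label), **pcfg
                    )
                    records, truth_table = generate_promoters(pdesign)
                    fasta = outdir / f"promoters_class{label}.fasta"
                    write_fasta(records, fasta)
                    emit(f"promoters_class{label}", fasta)
                    promoter_sets[int(label)] = records
        else:
            catalog = load_catalog(config.inputs["catalog"])
            ratios = pd.read_csv(config.inputs["ratios"], sep="\t", index_col="gene_id")
            pvalues = pd.read_csv(config.inputs["pvalues"], sep="\t", index_col="gene_id")
            promoter_sets = None
            if config.inputs.get("promoters"):
                promoter_sets = {"all": read_promoters(config.inputs["promoters"])}

        # ------------------------------------------------- trinarize
        stage = "trinarize"
        alpha = (
            config.alpha
            if config.alpha is not None
            else bonferroni_alpha(0.05, ratios.shape[1])
        )
        manifest["parameters"]["alpha"] = alpha
        tm = trinarize(ratios, pvalues, alpha)
        tm.write(outdir / "trinary.tsv")
        emit("trinary", outdir / "trinary.tsv")

        # --------------------------------------------------- cluster
        stage = "cluster"
        invariant, variable = split_invariant(tm)
        if config.k is None:
            selection = choose_k(
                variable, config.k_candidates, n_runs=config.n_runs, seed=config.seed
            )
            selection.diagnostics.to_csv(outdir / "k_selection.tsv", sep="\t")
            emit("k_selection", outdir / "k_selection.tsv")
            k = selection.selected_k
            manifest["parameters"]["selected_k"] = k
        else:
            k = config.k
        manifest["parameters"]["k"] = k
        assign = classify(tm, k=k, n_runs=config.n_runs, seed=config.seed)
        assign.write(outdir / "classes.tsv", sidecar=outdir / "classes.meta")
        emit("classes", outdir / "classes.tsv")
        dendro = cluster_experiments(variable, n_groups=min(4, len(tm.experiments)))
        pd.Series(dendro.group_of(), name="group").rename_axis("experiment").to_csv(
            outdir / "experiment_groups.tsv", sep="\t"
        )
        emit("experiment_groups", outdir / "experiment_groups.tsv")

        # ------------------------------------------------- associate
        stage = "associate"
        composition = compose_classes(assign, catalog)
        composition.write(outdir / "class_composition.tsv")
        emit("class_composition", outdir / "class_composition.tsv")
        means, counts = class_by_experiment_means(assign, ratios)
        means.to_csv(outdir / "class_experiment_means.tsv", sep="\t")
        emit("class_experiment_means", outdir / "class_experiment_means.tsv")

        # -------------------------------------------------- families
        stage = "families"
        fam_rows = []
        for focal in sorted(set(assign.labels.values())):
            if focal == 0:
                continue
            st = alternative_stats(assign, catalog, focal_class=focal)
            fam_rows.append(
                {
                    "focal_class": st.focal_class,
                    "n_genes": st.n_genes_in_class,
                    "families_with_class": st.n_families_with_class,
                    "families_with_alternative": st.n_families_with_alternative,
                    "pct_alternative": st.pct_alternative,
                }
            )
        pd.DataFrame(fam_rows).to_csv(
            outdir / "family_alternatives.tsv", sep="\t", index=False
        )
        emit("family_alternatives", outdir / "family_alternatives.tsv")

        # --------------------------------------------------- network
        stage = "network"
        plasto = [
            g for g, c in assign.labels.items()
            if catalog[g].compartment == "plasto" and c != 0 and g in ratios.index
        ]
        net_genes = plasto if len(plasto) >= 3 else list(variable.genes)
        corr, excluded = correlation_matrix(ratios.loc[net_genes])
        cg = build_network(
            corr,
            catalog,
            threshold=config.network.get("threshold", 0.75),
            mode=config.network.get("mode", "on_r2"),
        )
        write_sif(cg, outdir / "network.sif")
        write_graphml(cg, outdir / "network.graphml")
        cg.connector_report().to_csv(outdir / "connectors.tsv", sep="\t", index=False)
        for name in ("network.sif", "network.graphml", "connectors.tsv"):
            emit(name, outdir / name)
        blocks = find_blocks(
            corr,
            threshold=config.blocks.get("threshold", 0.8),
            mode=config.blocks.get("mode", "on_r"),
        )
        pd.DataFrame(
            [
                {"block": i + 1, "size": len(b.members), "density": b.density,
                 "min_stat": b.min_stat, "members": ",".join(b.members)}
                for i, b in enumerate(blocks)
            ]
        ).to_csv(outdir / "blocks.tsv", sep="\t", index=False)
        emit("blocks", outdir / "blocks.tsv")

        # ---------------------------------------------------- motifs
        stage = "motifs"
        if promoter_sets:
            pool = [rec for records in promoter_sets.values() for rec in records]
            occ_rows = []
            for motif in config.motifs:
                profiles = {
                    label: scan(records, motif)
                    for label, records in promoter_sets.items()
                }
                occ_rows.append(class_occupancy(profiles))
                env = background_envelope(
                    pool,
                    motif,
                    set_size=min(len(r) for r in promoter_sets.values()),
                    n_resamples=config.envelope.get("n_resamples", 200),
                    seed=config.seed,
                )
                for label, prof in profiles.items():
                    envelope_table(prof, env).to_csv(
                        outdir / f"motif_{motif.name}_class{label}_bins.tsv",
                        sep="\t", index=False,
                    )
                    emit(
                        f"motif_{motif.name}_class{label}_bins",
                        outdir / f"motif_{motif.name}_class{label}_bins.tsv",
                    )
            pd.concat(occ_rows, ignore_index=True).to_csv(
                outdir / "motif_occupancy.tsv", sep="\t", index=False
            )
            emit("motif_occupancy", outdir / "motif_occupancy.tsv")

        manifest["stages"] = [
            "simulate" if config.synthetic else "load",
            "trinarize", "cluster", "associate", "families", "network", "motifs",
        ]
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
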