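# Methods

## Overview

`riboclass` implements a meta-analysis workflow for the transcriptional
regulation of ribosomal-protein (RP) genes under stress. Plant genomes
carry hundreds of RP genes serving three ribosomes — cytosolic
(cytoRP), mitochondrial (mitoRP) and plastid (plastoRP) — organized in
small paralog families. The workflow asks three questions: do RP genes
fall into reproducible stress-response classes; do those classes track
the ribosome compartment the protein serves; and do class-specific
promoter elements (site II, telo-box) explain the classing.

The pipeline stages are: trinary significance coding of per-experiment
log-ratios, consensus k-means classing of genes, agglomerative
clustering of experiments, class x localization association,
family-level "transcriptional alternative" statistics, thresholded
Pearson co-expression networks with connector genes, and positional
promoter-motif enrichment against a random-cluster envelope. A
synthetic-data generator plants known structure so every stage is
testable without any external database.

## Trinary coding

Each (gene, experiment) pair carries a log-ratio and a p-value, as
published by two-color array pipelines. The code is

    c = sign(ratio)  if p < alpha,  else 0,

with a ratio of exactly zero coding 0 (its sign is undefined). The
default `alpha` is 0.05/n_experiments (Bonferroni over the experiments
each gene is tested in, 0.05/49 for the default design), holding the
family-wise error of a gene's whole row at 5% so that "invariant"
genes (all-zero rows, class 0) are called conservatively. The original
platform's exact significance definition is not restated in the
sources this package follows, so `alpha` is configuration, not dogma.
Coding is monotone in `alpha` by construction: a nonzero code at a
stricter threshold survives any looser one.

## Consensus k-means classing

Genes with at least one nonzero code are clustered by k-means on their
raw trinary rows (Euclidean distance; the codes are ordinal, -1 < 0 <
+1). Because single k-means fits depend on initialization, the fit is
repeated `n_runs = 50` times, each run an independently seeded k-means
taking the best of `n_init = 10` random starts. Run labelings are
aligned to the lowest-inertia run by exact maximum-agreement assignment
on the k x k contingency table (Hungarian matching); each gene then
receives the modal aligned label, with ties broken toward the lower
label index and counted. Per-gene *stability* — the fraction of runs
agreeing with the modal label — is the consensus diagnostic.

Two choices matter here and were made after observing failure modes on
synthetic data:

* **Reference run.** Aligning all runs to an arbitrary first run is
  fragile: when that run is a poor local optimum, the matching becomes
  ambiguous and a single planted class's votes can split across two
  labels, collapsing the consensus. Aligning to the lowest-inertia run
  removes the failure mode at no cost.
* **Converged runs.** With single-start runs, a merged three-class
  solution can appear exactly as reproducible as the correct
  four-class one. With best-of-10 runs, each run reports a
  well-converged optimum; the class count whose optimum is *unique*
  (k = 4 on four-class data) then reaches stability ~1.0 while smaller
  and larger k trade off competing merges and splits. This is what
  makes mean stability a usable model-selection signal.

`choose_k` compares candidate class counts (default 3-5) on mean
stability, ties going to the smaller k; the class-size balance
(coefficient of variation) and tie frequency are reported alongside.
The selection is reported, never silently applied. Class labels are
finally renumbered 1..k by descending class size, with ties broken on
the lexicographic order of class mean profiles, so equivalent
assignments are literally equal and invariant to gene order; label 0
is reserved for invariant genes.

Experiments are clustered by average-linkage agglomeration on the mean
absolute difference of their trinary columns (Manhattan distance
divided by the gene count), cut to a requested group number.

## Synthetic study design

The default generator emulates a 49-experiment stress compendium with
five planted classes sized to the headline membership of the study
system (47 invariant, 132 erratic, 68 + 32 + 14 coherent). Experiments
carry group labels: 12 biotic, 10 abiotic, 10 weak, 12 carbon/nitrogen
(C/N) status, 2 UV and 3 nitrogen-re-supply comparisons. The
allocation was fixed up front so each coherent class responds in >20
experiments, which sets the recovery power at the default effect.

Planted mean log-ratio profiles, per class:

| class | C/N status | biotic | abiotic | UV | N re-supply |
|------|-----------|--------|---------|----|-------------|
| 0 invariant | 0 | 0 | 0 | 0 | 0 |
| 1 erratic | random 2-4 experiments anywhere, random sign | | | | |
| 2 cytoRP-like | -e | +e | 0 | 0 | +e |
| 3 plastoRP nuclear | -e | 0 | +e | -e | +e |
| 4 plastoRP plastidial | -e | 0 | -e | +e | -e |

with `e = effect_size` (default 1.5) on the log-ratio scale and i.i.d.
Gaussian noise `noise_sd` (default 0.5, a standardized effect of 3).
Class 2's positive response to nitrogen re-supply encodes recovery
from N-starvation repression; it also makes all six experiment groups
distinguishable by their class-response profiles, without which the
experiment clustering could never separate the abiotic and re-supply
groups. Classes 3 and 4 are fully opposed in abiotic, UV and re-supply
responses, the discriminators of the two plastid classes.

P-values are the two-sided z-test of each ratio against zero at the
known noise scale, so null cells are Uniform(0,1) and the coding
threshold acts on internally consistent data. At the default
standardized effect of 3 and Bonferroni threshold (|z| > 3.28), the
per-cell detection probability is only ~0.39 — deliberate: class
recovery must rest on profile-wide evidence, not single cells. What
the generator does **not** model: probe-level physics, normalization
and dye bias, correlated replicate structure, and non-i.i.d. promoter
sequence composition (see below). Passing tests therefore demonstrate
algorithmic correctness and statistical behavior under the declared
model, not performance on any real compendium.

Expected recovery under the defaults (effect/noise = 3, balanced
four-class design of 60 genes each): adjusted Rand index vs truth
0.92-0.99 and k = 4 selected, across seeds. With the skewed
default sizes the 14-gene class is harder to protect and ARI
drops to ~0.82-0.95 — a genuine property of consensus k-means on very
unbalanced data, reported as such.

## Family alternatives and set algebra

For a focal class, families (grouped purely by family label) are
counted that contain at least one *studied* focal-class gene; among
those, families also containing a studied member in any other class
(class 0 included) count as having a transcriptional alternative. The
percentage is the ratio of the two counts, rounded half-up. "Studied"
restricts to genes with probes on the platform under analysis, so the
fraction is an underestimate whenever paralogs lack probes. Venn
decompositions are exact region partitions of 2-3 named sets.

## Co-expression structure

Pearson correlation is computed across samples per gene pair;
zero-variance genes are excluded with a warning list. Because the
literature quotes both r and r-squared thresholds for the same
figures, both modes are first-class (`on_r`, `on_r2`); under `on_r2`
anti-correlated edges pass and carry their sign. Co-regulation
*blocks* are connected components of the thresholded graph (default
r >= 0.8), the reproducible analogue of blocks read off a correlation
heat map; components below a minimum size (default 2) are dropped from
the block report only. The *network* (default r^2 >= 0.75) carries
compartment and genome node attributes, and its *connector* genes are
articulation points — nodes whose removal increases the component
count, the graph-theoretic form of "the gene linking the nuclear and
plastidial expression clouds". Mean-level contrasts return per-group
means with standard errors and a ratio with first-order propagated SE.

## Promoter motif enrichment

Motifs are degenerate IUPAC consensus strings scanned exactly
(forward strand by default; both motifs are coding-strand promoter
elements). Coordinates are 3'-anchored: the final base of the supplied
upstream sequence is -1 and a hit sits at its first base's offset;
sequences are truncated to their last 1000 nt first. Built-in motifs:
site II `ARGCCCA` with window -70 +/- 25 and telo-box `AAACCCWA` with
window -30 +/- 25. All overlapping matches count in the 50-nt
non-overlapping positional histogram (sum-conserving, step
configurable); occupancy is a per-promoter indicator, so multiplicity
cannot inflate it; window membership is boundary-inclusive on the hit
start. An `N` in a sequence matches only an `N` in the motif.

The background envelope draws `n_resamples` subsets (without
replacement) of `set_size` promoters from a pool, and flags each class
histogram bin as above/within/below mean +/- 2.5 SD after rescaling
the class histogram to `set_size`. Two numerical caveats are
documented rather than hidden: (i) with an i.i.d. background at GC
0.36 the chance site-II rate is ~0.05 hits per promoter, so small
pools leave bins with zero observed background and a degenerate
envelope — the bundled experiments use a 4000-promoter pool and
200-promoter classes so each bin's dispersion is estimable; (ii)
subset resampling slightly understates the variance of an
*independent* promoter set of the same size (finite-population
shrinkage), making the 2.5-SD band mildly anti-conservative for
motif-free classes.

## Degenerate inputs and tie-breaks

Duplicate gene IDs, unknown compartment/genome tokens, shape
mismatches, p-values outside [0,1], overlapping control/RP sets,
empty gene sets and undersized pools are hard errors naming the
offender. Empty summary cells are missing, never zero. All stochastic
steps take explicit seeds; a fixed seed reproduces every table
byte-identically (the run manifest records SHA-256 digests to prove
it).

## Problem sizes

The bundled experiments run at desk scale: 287-467 genes x 49
experiments for clustering (50 consensus runs x 3 candidate k), 1000
null genes for calibration, 200-promoter classes against a
4000-promoter pool with 300 resamples for motif enrichment. The full
test suite completes in well under a minute.

## Known limitations

* The stability criterion for choosing k is a declared stand-in for an
  undefined "most efficient class number"; it behaves well on planted
  data but is not a claim about the original procedure.
* Consensus k-means protects small classes poorly when class sizes are
  very skewed (the 14-gene class); a model-based alternative is out of
  scope by design.
* The i.i.d. promoter background cannot reproduce the ~30% chance
  occupancy real intergenic sequence shows for these motifs; absolute
  occupancies of real promoter sets are not comparable to the
  generator's, only the positional-enrichment logic is.
* Catalog construction (homology, phylogeny, localization prediction)
  is out of scope; the catalog is an input.
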