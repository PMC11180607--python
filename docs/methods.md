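# Methods

This note documents the models, defaults and numerical choices behind
`celltagmulti`, and what its synthetic benchmarks do and do not show.

## Barcode model and extraction

A CellTag barcode is a fixed layout of random runs and constant spacers
(built-in designs: `v1`, 18 random bases in 28 total; `v0`, 25 random
bases in 37 total). Extraction scans a read for the leftmost position at
which **every spacer matches exactly** and returns the concatenated random
bases. Spacer mismatches are not tolerated; a read whose spacer carries a
sequencing error is rejected rather than risk a frame-shifted extraction,
and errors in the random bases are instead repaired downstream by
allowlist correction. For ATAC-derived amplicons the reverse complement is
scanned when the forward strand fails (amplicons may be sequenced in
either orientation); 3'-capture RNA reads are stranded, so RNA extraction
scans the forward strand only. Random segments containing `N` are
rejected: an `N` cannot be scored consistently against an allowlist.

Allowlist correction snaps an observed random segment to the **unique**
allowlist entry within `max_hamming` substitutions (default 1). Exact
matches return at distance 0. When two or more entries tie at the minimum
distance the read is rejected — a wrong correction merges unrelated clones,
which is the costlier error; an optional mode breaks ties toward the
most abundant entry for users who prefer recall. Indel (Levenshtein)
correction is out of scope: the layouts are fixed-length and indels
break the spacer frame anyway. Every rejection is tallied by reason
(`no pattern` / `no allowlist match` / `ambiguous`), and
`matched + rejected == total` always holds.

## Count matrices and signatures

RNA CellTag counts are deduplicated UMI counts per (cell, tag); ATAC
counts are read counts (the amplicon carries no UMI). Binarization keeps
tags with **count ≥ 2** ("more than one" molecule — a single molecule is
indistinguishable from ambient contamination or index hopping), and cells
are retained when their signature size falls in a modality-dependent
range: 2–25 for RNA, 1–25 for ATAC by default. A lone RNA tag is more
likely ambient than a true one-tag clone, while ATAC capture is sparser,
so singletons carry real signal there; both bounds are configurable (some
experimental designs use 1–25 for both modalities). An optional filter
additionally removes single-tag cells whose tag also occurs inside any
multi-tag signature: such a cell cannot be distinguished from a dropout-
afflicted member of the multi-tag clone. Per-cell drop reasons are
recorded for QC. Matrices serialize as Matrix Market (`.mtx`) with sidecar
cell/tag name TSVs.

Library QC metrics: amplicon complexity is the number of distinct
(cell barcode, UMI, CellTag) triples; the species-mixing cross-talk
statistic is the percent of cells (with ≥ 2 CellTag reads) whose fraction
of reads from their species' own library falls below 0.95.

## Clone calling

Cells are compared by the Jaccard similarity of their binary signatures
over the union tag universe; an edge joins two cells when J ≥ 0.6 for
same-modality pairs or J ≥ 0.5 for RNA-vs-ATAC pairs (cross-modality
capture differs in depth, so a 3-of-6-tag overlap should merge — which is
also why the thresholds are **inclusive**). Clones are the **connected
components** of this graph. Components are the minimal clustering
consistent with "cells linked above threshold belong together", are
invariant to cell order and tag relabeling, and coarsen monotonically as
the threshold drops. Clone identifiers are deterministic: descending
size, ties by lexicographically smallest member.

Fate annotation assigns each clone the modal cell type among its
fate-time-point siblings, optionally after grouping scarce lineages
(e.g. Ery/Meg; Baso/Eos/Mast; DCs), with fate bias the fraction of those
siblings in the modal group. Modal-count ties are broken toward the group
whose dominant raw type is most numerous, then lexicographically, with a
tie flag set. Cross-replicate homoplasy is observed as the fraction of
cells whose exact signature also occurs in an independently infected
replicate (shared descent is impossible there, so set-equal signatures
must be collisions); cells, not distinct signatures, are counted.

Clonal coherence across modalities is quantified by Spearman correlation
between clone-averaged expression (RNA members) and clone-averaged
gene-score/activity profiles (ATAC members), within clones versus across
all ordered clone pairs.

## Homoplasy simulation

Each of `n_cells` founders draws `k ~ Poisson(moi)`, rejection-resampled
into `tag_range` (default 1–25): zero-tag cells are unobservable and more
than ~25 integrations is implausible. `moi` is the untruncated Poisson
mean; rejection raises the realized mean (3.52 tags/cell at MOI 3.4, 2.52
at MOI 2.25 — the simulator reports the realized value). Tags are drawn
**without replacement** within a cell (double integration of one barcode
is invisible), uniformly over the library or weighted by allowlist
abundance when weights are supplied. Uniform is the default because
sequenced libraries' abundance profiles vary batch-to-batch; a skewed
profile raises the collision rate, so the uniform estimate is a lower
bound. The homoplasy rate of one simulation is the number of cells whose
exact tag set equals another scored cell's, divided by the number of
scored cells (optionally by the full simulated population, for reporting
collision burden against the experiment size); the expectation is the
mean over `n_sims` (default 100) independent simulations, deterministic
given the seed. The reprogramming-style configuration first applies the
same ambiguous-singleton exclusion used in clone calling.

Validation: with `k ≡ 1` and a uniform library of size L the per-cell
collision probability has the closed form `1 − (1 − 1/L)^(n−1)`, and the
simulator agrees within Monte-Carlo error; the rate falls with library
size and MOI and rises with population size. The implementation draws
with replacement and rejects per-cell duplicates, which is exact and much
faster than per-cell `choice(replace=False)` since duplicates are rare
for k ≪ √L.

## Clone–cell graphs and subclone statistics

For joint embedding, one abstract node per clone (or per subclone — a
clone split by time point × assay, at most four pieces in a 2 × 2 design)
is added to the cell–cell kNN graph with an edge to each member cell.
Cell–cell edges are never modified. The clone-edge weight is the mean of
the member cell's incident kNN weights (`mean_incident`, default), which
keeps clone edges on the local similarity scale of each cell; a constant
weight is available for sensitivity analysis. The 2-D layout itself
(UMAP graph layout, ForceAtlas) is delegated to external engines via the
edge-list export.

Subclone overlap is the exact Wasserstein distance between the RNA and
ATAC subclone point clouds of each fate-group pair, in an embedding of
the subclone nodes (30-D in the reference workflow). Order 1 is the
default (order 2 available); the transport LP is solved exactly with
HiGHS (`scipy.optimize.linprog`), and tests verify it against an
independent assignment-expansion oracle to 1e-8. With five fate groups
this yields 5 intra-lineage (same group, RNA vs ATAC) and 20
inter-lineage distances.

The closeness metric of a state subclone is its minimum Euclidean
distance to the centroid of any *alternative* fate group — larger means
deeper inside its own fate territory. The percentile curve reports the
mean fate bias of subclones at or above each closeness percentile; at
percentile 0 it equals the overall mean.

## State–fate prediction

Datasets pair state-time-point cells with their clone's fate label.
Combined-modality samples are formed per clone by a seeded random
bijection between min(#RNA, #ATAC) state siblings, concatenating the two
feature vectors; surplus siblings are dropped rather than reused, to
avoid weighting clones by their capture imbalance. ATAC TF-activity
features can be smoothed by k-nearest-neighbor imputation (k = 20
default, self included) in a reduced embedding.

Cross-validation is repeated stratified k-fold (n_splits = 5,
n_repeats = 5 → 25 accuracy and 25 weighted-F1 values). By default all
samples of a clone are kept in one fold (`StratifiedGroupKFold`):
siblings share ancestry and features, so splitting them across folds
leaks test information into training. A literal per-cell stratified
split is available for comparison. Hyperparameters are selected by a
nested grid search on training folds only; the default grids cover
n_estimators/max_depth/min_samples_leaf/bootstrap for random forest,
num_leaves/max_depth/min_data_in_leaf/bagging/feature_fraction for
LightGBM, and penalty/C/solver for logistic regression. Tests and the
bundled examples use single-point or reduced grids; the full grids are
for real analyses.

Model interpretation uses **interventional Shapley values**, computed
in-package: the value of a feature subset is the expected model output
with that subset pinned to the explained sample and the rest drawn from a
background sample of the training fold. Exact subset enumeration
(2^p × n_background evaluations per sample) is used up to 12 features and
satisfies additivity exactly (base value + attributions = model output);
a permutation-sampling estimator covers larger feature counts. Each data
point appears in one test fold per repeat, so its n_repeats attribution
vectors are averaged before summarizing into mean-|value| importance and
the Pearson correlation between a feature's values and its attributions
per fate (the sign separates drivers from suppressors). Exact
enumeration is exponential in the feature count by design; genome-scale
feature spaces should be pre-reduced or use the permutation estimator.

Differential enrichment between fate-destined groups is one-vs-rest
two-sided Mann–Whitney–Wilcoxon per feature with Benjamini–Hochberg
adjustment across features (step-up, implemented in-package and verified
against statsmodels). Effect sizes: log2 fold-change of means with
pseudocount 1 for count-derived features, difference of means for
z-scored activities; enrichment requires adjusted p < 0.05 and effect
above threshold, and "uniquely enriched" marks features passing in
exactly one group. TF activities can be pre-filtered by requiring
Pearson r ≥ 0.3 between a TF's activity and its own gene score, removing
motif-family artefacts.

## Synthetic experiment generator

The generator emulates the structure of a two-time-point, two-modality
CellTagging experiment: founders tagged exactly as in the homoplasy
simulator (default MOI 3.4, 1–25 tags, 25,000-barcode library), geometric
clone sizes (mean 5; heavy right tail as seen for expanding clones),
cells split evenly across (time point × modality), per-tag dropout at
capture (default 0.1, standing in for modality capture differences),
per-base substitution errors (default 0.5%), 3 UMIs × 2 reads per RNA
tag and 3 reads per ATAC tag, and random read orientation for ATAC.
Features are per-fate Gaussian mean shifts (disjoint feature blocks,
default 2 SD effect, unit noise) on state cells, with per-cell fate
adherence 0.9. The `half` signal mode defines four fates as combinations
of two binary factors, RNA features encoding only the first and ATAC
only the second — each modality alone can resolve at most half the fate
classes, so combined features should win; this is the scenario used to
validate the multi-omic gain qualitatively.

What passing tests on these fixtures show: the pipeline's bookkeeping,
filtering and clustering are correct, and the harness detects planted
signal at the expected strength. What they do not show: performance on
real data, which has ambient contamination, barcode silencing, clonal
selection between tagging and sampling, non-Gaussian counts and
batch structure — none of which the generator models.

## Problem sizes and reproducibility

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical inputs give byte-identical
outputs. The bundled acceptance script runs the two reference homoplasy
configurations at full published size (5,500 and 30,000 cells, 100
simulations each; ~10 s total). Test fixtures use hundreds of clones and
thousands of cells — large enough for the planted-recovery and
cross-validation checks to be stable, small enough to run in seconds —
and every fixture is generated programmatically at test time. Known
numerical edge cases: Jaccard and rank-based statistics are undefined on
empty sets/groups and raise; Wasserstein clouds must be non-empty;
correlation of a constant feature is reported as NaN rather than 0.
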