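# celltagmulti

Multi-omic lentiviral barcode lineage tracing: extraction and
error-correction of CellTag barcodes from single-cell RNA and ATAC reads,
clone calling across modalities, homoplasy simulation, clone–cell graph
construction for joint embedding, and state–fate prediction with model
interpretation.

## The problem

CellTagging delivers heritable random DNA barcodes (CellTags) to cells by
lentivirus; each founder cell receives a random *set* of barcodes (its
CellTag signature), which its descendants inherit. Capturing signatures in
both scRNA-seq and scATAC-seq lets clones be tracked across modalities, so
a cell's early transcriptional and chromatin state can be linked to the
eventual fate of its clone ("state–fate" analysis). This package
implements the computational side of that workflow for users of
CellTag-multi-style experiments:

1. **Barcode extraction** — parse reads against a barcode layout such as
   v1 (`N3 GT N3 CT N3 AG N3 TG N3 CA N3`; 18 random bases interleaved with
   fixed spacers) and snap sequencing errors in the random bases to a
   sequenced allowlist of valid barcodes (unique match within Hamming
   distance 1 by default; ties rejected).
2. **Signatures** — build cells × CellTag count matrices (UMI counts for
   RNA, read counts for ATAC), binarize at ≥2 counts, and keep cells with a
   plausible number of tags (2–25 for RNA, 1–25 for ATAC by default).
3. **Clone calling** — connect cells whose signatures have Jaccard
   similarity J ≥ 0.6 (same modality) or J ≥ 0.5 (RNA vs ATAC) and take
   connected components as clones; annotate each clone with a fate label
   (modal cell type among fate-time-point siblings) and fate bias (the
   fraction of those siblings in the modal type).
4. **Homoplasy simulation** — estimate the probability that two founders
   independently draw identical signatures (which falsely merges clones):
   each of *n* cells draws `k ~ Poisson(MOI)` barcodes, truncated to
   1–25, without replacement from the library; the homoplasy rate is the
   fraction of cells whose exact signature recurs, averaged over 100
   simulations.
5. **Clone–cell graphs** — impute abstract clone/subclone nodes into a
   cell–cell kNN graph for joint 2-D embedding, plus subclone statistics:
   exact Wasserstein overlap between RNA and ATAC subclone clouds, and a
   closeness-vs-fate-bias percentile curve.
6. **State–fate prediction** — repeated stratified k-fold cross-validation
   (5 × 5 = 25 accuracy / weighted-F1 values) of fate classifiers
   (random forest, LightGBM, logistic regression) on single-modality or
   combined (randomly paired RNA + ATAC sibling) features, with
   interventional Shapley-value interpretation and rank-sum / 
   Benjamini–Hochberg differential feature enrichment.

A synthetic-experiment generator (`celltagmulti.sim`) produces reads,
matrices, metadata and fate-linked features with known ground truth, so
the full pipeline is testable without any sequencing data.

## Worked example

```python
from celltagmulti import (
    BinarySignatureSet, CloneCallParams, HomoplasySimParams,
    call_clones, expected_homoplasy,
)

# Expected homoplasy for a 5,500-cell experiment tagged at MOI 3.4
# from a 25,000-barcode library (100 simulations)
params = HomoplasySimParams(n_cells=5_500, moi=3.4, tag_range=(1, 25),
                            library=25_000, n_sims=100, seed=7)
result = expected_homoplasy(params)
print(f"expected homoplasy rate: {result.mean_rate:.4f}")
print(f"realized mean tags/cell: {result.realized_mean_tags:.2f}")

# Clone calling across modalities from binary CellTag signatures
rna = BinarySignatureSet(
    signatures={"rna_1": frozenset("ABC"), "rna_2": frozenset("ABC"),
                "rna_3": frozenset("XY")},
    min_count=2, tag_range=(2, 25), modality="RNA")
atac = BinarySignatureSet(
    signatures={"atac_1": frozenset("ABCDEF")},
    min_count=2, tag_range=(1, 25), modality="ATAC")
table = call_clones([rna, atac], CloneCallParams(tau_intra=0.6, tau_cross=0.5))
print(table.cells[["clone_id", "cell", "modality"]].to_string(index=False))
```

Output:

```
expected homoplasy rate: 0.0030
realized mean tags/cell: 3.52
 clone_id   cell modality
        0 atac_1     ATAC
        0  rna_1      RNA
        0  rna_2      RNA
        1  rna_3      RNA
```

About 0.3% of founders are expected to share a signature at this library
size and MOI (safe for clone calling), and the realized tags/cell exceed
the nominal MOI because zero-tag cells are unobservable. In the clone
call, the two identical RNA cells (J = 1 ≥ 0.6) merge with the ATAC cell
whose six-tag signature contains theirs (J = 3/6 = 0.5 ≥ 0.5), while the
unrelated RNA cell stays a singleton clone.

The same steps are available from the shell:

```bash
celltag homoplasy --n-cells 5500 --moi 3.4 --library-size 25000 --n-sims 100 --seed 7
celltag extract --pattern v1 --allowlist allow.csv --in reads.tsv --out-dir out/
celltag matrix --in out/tags.tsv --out-dir out/
celltag clones --in out/signatures.tsv --tau-intra 0.6 --tau-cross 0.5 --out-dir out/
```

Every subcommand writes a `manifest.json` (configuration, package version,
input checksums) so runs can be reproduced exactly.

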