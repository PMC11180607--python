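"""Cell x CellTag count matrices, signature binarization/filtering and QC.

RNA counts are deduplicated UMI counts; ATAC counts are read counts (ATAC
amplicons carry no UMI). Signatures are obtained by binarizing counts at
``>1`` (i.e. >=2) and keeping cells whose number of detected CellTags falls
in a plausible range (2-25 for RNA, 1-25 for ATAC by default — a lone tag in
RNA is more likely ambient contamination, while ATAC capture is sparser so
singletons are kept). The cross-talk statistic from the human/mouse
species-mixing control quantifies barcode leakage between two co-processed
libraries.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .reads import ATAC, RNA, CellTagHit

#: Default binarization/filter parameters per modality: (min_count, (lo, hi)).
DEFAULT_FILTERS = {RNA: (2, (2, 25)), ATAC: (2, (1, 25))}


@dataclass
class CellTagMatrix:
    """Sparse cells x CellTags count matrix with sample metadata."""

    cells: list[str]
    tags: list[str]
    counts: sp.csr_matrix
    modality: str
    sample_id: str = "sample"
    time_point: str | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cells), len(self.tags)):
            raise ValueError("counts shape does not match cells x tags")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        """Dense DataFrame view (small matrices only)."""
        return pd.DataFrame(
            self.counts.toarray(), index=self.cells, columns=self.tags
        )


def build_count_matrix(
    hits: Iterable[CellTagHit],
    modality: str | None = None,
    sample_id: str | None = None,
    time_point: str | None = None,
) -> CellTagMatrix:
    """Aggregate extracted hits into a cells x tags count matrix.

    RNA: counts distinct UMIs per (cell, tag); duplicate reads of one UMI
    collapse. ATAC: counts reads per (cell, tag). Cell and tag orderings are
    lexicographic, so the result is independent of read order.
    """
    hits = list(hits)
    modalities = {h.modality for h in hits}
    if modality is None:
        if len(modalities) > 1:
            raise ValueError(f"mixed modalities in hit stream: {sorted(modalities)}")
        modality = modalities.pop() if modalities else RNA
    elif modalities - {modality}:
        raise ValueError(f"hits contain modalities {sorted(modalities)} != {modality}")
    samples = {h.sample_id for h in hits}
    if sample_id is None:
        if len(samples) > 1:
            raise ValueError(f"mixed samples in hit stream: {sorted(samples)}")
        sample_id = samples.pop() if samples else "sample"

    if modality == RNA:
        if any(h.umi is None for h in hits):
            raise ValueError("RNA hits must carry UMIs")
        units = {(h.cell_barcode, h.celltag, h.umi) for h in hits}
        pairs = [(c, t) for c, t, _ in units]
    else:
        pairs = [(h.cell_barcode, h.celltag) for h in hits]

    cells = sorted({c for c, _ in pairs})
    tags = sorted({t for _, t in pairs})
    ci = {c: i for i, c in enumerate(cells)}
    ti = {t: i for i, t in enumerate(tags)}
    mat = sp.coo_matrix(
        (
            np.ones(len(pairs), dtype=np.int64),
            ([ci[c] for c, _ in pairs], [ti[t] for _, t in pairs]),
        ),
        shape=(len(cells), len(tags)),
    ).tocsr()
    return CellTagMatrix(
        cells=cells,
        tags=tags,
        counts=mat,
        modality=modality,
        sample_id=sample_id,
        time_point=time_point,
    )


@dataclass
class BinarySignatureSet:
    """Per-cell CellTag signatures after binarization and tag-range filtering."""

    signatures: dict[str, frozenset[str]]
    min_count: int
    tag_range: tuple[int, int]
    modality: str | None = None
    drop_reasons: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["cell", "reason"])
    )

    @property
    def cells(self) -> list[str]:
        return list(self.signatures)

    def __len__(self) -> int:
        return len(self.signatures)


def binarize_and_filter(
    m: CellTagMatrix,
    min_count: int | None = None,
    tag_range: tuple[int, int] | None = None,
) -> BinarySignatureSet:
    """Binarize counts at ``>= min_count`` and keep cells within ``tag_range``.

    Defaults follow the modality (:data:`DEFAULT_FILTERS`). A per-cell drop
    reason table records the filtering funnel for QC.
    """
    d_min, d_range = DEFAULT_FILTERS.get(m.modality, DEFAULT_FILTERS[RNA])
    if min_count is None:
        min_count = d_min
    if tag_range is None:
        tag_range = d_range
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    lo, hi = tag_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid tag_range {tag_range}")

    binary = m.counts >= min_count
    binary = sp.csr_matrix(binary)
    sizes = np.asarray(binary.sum(axis=1)).ravel()
    signatures: dict[str, frozenset[str]] = {}
    dropped = []
    tags = np.asarray(m.tags, dtype=object)
    for i, cell in enumerate(m.cells):
        k = sizes[i]
        if k < lo:
            dropped.append((cell, "too-few-tags"))
        elif k > hi:
            dropped.append((cell, "too-many-tags"))
        else:
            row = binary.indices[binary.indptr[i] : binary.indptr[i + 1]]
            signatures[cell] = frozenset(tags[row])
    return BinarySignatureSet(
        signatures=signatures,
        min_count=min_count,
        tag_range=(lo, hi),
        modality=m.modality,
        drop_reasons=pd.DataFrame(dropped, columns=["cell", "reason"]),
    )


def drop_ambiguous_singletons(s: BinarySignatureSet) -> BinarySignatureSet:
    """Remove single-CellTag cells whose tag also occurs in a multi-tag signature.

    A lone, highly abundant tag cannot distinguish a true one-tag clone from
    ambient leakage out of a multi-tag clone, so such cells are dropped to
    limit false clone merging. Multi-tag cells are never touched.
    """
    multi_tags: set[str] = set()
    for sig in s.signatures.values():
        if len(sig) >= 2:
            multi_tags.update(sig)
    kept = {}
    dropped = []
    for cell, sig in s.signatures.items():
        if len(sig) == 1 and next(iter(sig)) in multi_tags:
            dropped.append((cell, "singleton-ambiguous"))
        else:
            kept[cell] = sig
    reasons = pd.concat(
        [s.drop_reasons, pd.DataFrame(dropped, columns=["cell", "reason"])],
        ignore_index=True,
    )
    return BinarySignatureSet(
        signatures=kept,
        min_count=s.min_count,
        tag_range=s.tag_range,
        modality=s.modality,
        drop_reasons=reasons,
    )


def tag_abundance(s: BinarySignatureSet) -> pd.Series:
    """Percent of (kept) cells whose signature contains each tag."""
    if not s.signatures:
        raise ValueError("empty signature set")
    counts: dict[str, int] = {}
    for sig in s.signatures.values():
        for t in sig:
            counts[t] = counts.get(t, 0) + 1
    n = len(s.signatures)
    return pd.Series(
        {t: 100.0 * c / n for t, c in sorted(counts.items())}, name="abundance_pct"
    )


def library_complexity(hits: Iterable[CellTagHit]) -> int:
    """Number of distinct (cell barcode, UMI, CellTag) combinations.

    A UMI-based complexity measure of a CellTag amplicon library; undefined
    for ATAC reads, which carry no UMI.
    """
    triples = set()
    for h in hits:
        if h.umi is None:
            raise ValueError("library_complexity requires UMI-bearing (RNA) hits")
        triples.add((h.cell_barcode, h.umi, h.celltag))
    return len(triples)


def species_crosstalk(
    per_cell_reads: Mapping[str, tuple[int, int]],
    species_of_cell: Mapping[str, str],
    expected_library: Mapping[str, str],
    min_reads: int = 2,
    purity_threshold: float = 0.95,
) -> tuple[pd.DataFrame, float]:
    """Species-mixing cross-talk: percent of cells below a purity threshold.

    ``per_cell_reads`` maps cell -> (reads from library X, reads from
    library Y); ``expected_library`` maps each species to its library
    ("X"/"Y"). Purity is the fraction of a cell's CellTag reads originating
    from the library matching its species. Cells with fewer than
    ``min_reads`` total CellTag reads are excluded; cross-talk is the percent
    of included cells with purity below ``purity_threshold``.
    """
    rows = []
    for cell, (x, y) in per_cell_reads.items():
        species = species_of_cell.get(cell)
        if species is None or species not in expected_library:
            raise ValueError(f"unknown species label for cell {cell!r}")
        total = x + y
        if total < min_reads:
            continue
        expected = x if expected_library[species] == "X" else y
        rows.append((cell, species, total, expected / total))
    table = pd.DataFrame(rows, columns=["cell", "species", "total_reads", "purity"])
    if len(table) == 0:
        return table, float("nan")
    pct = 100.0 * float((table["purity"] < purity_threshold).sum()) / len(table)
    return table, pct


# ---------------------------------------------------------------------------
# I/O: Matrix Market with sidecar cell/tag name TSVs


def write_mtx(m: CellTagMatrix, directory: str | Path, prefix: str = "celltag") -> None:
    """Write matrix.mtx + cells.tsv + tags.tsv + a small metadata JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / f"{prefix}.mtx"), m.counts.tocoo())
    pd.Series(m.cells).to_csv(
        directory / f"{prefix}.cells.tsv", sep="\t", index=False, header=False
    )
    pd.Series(m.tags).to_csv(
        directory / f"{prefix}.tags.tsv", sep="\t", index=False, header=False
    )
    meta = {"modality": m.modality, "sample_id": m.sample_id, "time_point": m.time_point}
    (directory / f"{prefix}.meta.json").write_text(json.dumps(meta) + "\n")


def read_mtx(directory: str | Path, prefix: str = "celltag") -> CellTagMatrix:
    """Read a matrix written by :func:`write_mtx`."""
    directory = Path(directory)
    counts = sp.csr_matrix(scipy.io.mmread(str(directory / f"{prefix}.mtx")))
    cells = pd.read_csv(
        directory / f"{prefix}.cells.tsv", sep="\t", header=None
    )[0].astype(str).tolist()
    tags = pd.read_csv(
        directory / f"{prefix}.tags.tsv", sep="\t", header=None
    )[0].astype(str).tolist()
    meta_path = directory / f"{prefix}.meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return CellTagMatrix(
        cells=cells,
        tags=tags,
        counts=counts.astype(np.int64),
        modality=meta.get("modality", RNA),
        sample_id=meta.get("sample_id", "sample"),
        time_point=meta.get("time_point"),
    )
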