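"""Tagged reads: containers, FASTQ/TSV input, and the extraction pipeline.

A :class:`TaggedRead` is one sequencing read from a CellTag amplicon library
whose cell barcode (and UMI, for RNA) were assigned upstream by the
single-cell platform. Cell demultiplexing and alignment are out of scope:
FASTQ input carries the assignments in the read description using the
documented ``CB:<cell>;UMI:<umi>`` dialect, and TSV input carries them as
columns.

:func:`extract_and_correct` runs pattern extraction and allowlist correction
over a read stream, keeping a per-reason rejection tally so that
``matched + rejected == total`` always holds.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .allowlist import Allowlist
from .patterns import BarcodePattern, extract_barcode

RNA = "RNA"
ATAC = "ATAC"
MODALITIES = (RNA, ATAC)


@dataclass(frozen=True)
class TaggedRead:
    """One read: cell barcode, optional UMI (RNA only), sequence, provenance."""

    cell_barcode: str
    umi: str | None
    read_sequence: str
    modality: str = RNA
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not self.read_sequence or not set(self.read_sequence) <= set("ACGTN"):
            raise ValueError("read_sequence must be nonempty over A/C/G/T/N")
        if (self.umi is None) == (self.modality == RNA):
            raise ValueError("umi must be present iff modality is RNA")


@dataclass(frozen=True)
class CellTagHit:
    """An extracted, allowlist-corrected CellTag observation."""

    cell_barcode: str
    umi: str | None
    celltag: str
    modality: str
    sample_id: str


@dataclass
class ExtractionStats:
    """Rejection tally for one extraction run."""

    total: int = 0
    matched: int = 0
    rejected_no_pattern: int = 0
    rejected_no_allowlist_match: int = 0
    rejected_ambiguous: int = 0
    counts_by_reason: dict = field(default_factory=dict)

    @property
    def rejected(self) -> int:
        return (
            self.rejected_no_pattern
            + self.rejected_no_allowlist_match
            + self.rejected_ambiguous
        )

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "matched": self.matched,
            "rejected": self.rejected,
            "rejected_no_pattern": self.rejected_no_pattern,
            "rejected_no_allowlist_match": self.rejected_no_allowlist_match,
            "rejected_ambiguous": self.rejected_ambiguous,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def extract_and_correct(
    reads: Iterable[TaggedRead],
    pattern: BarcodePattern,
    allowlist: Allowlist | None = None,
    max_hamming: int = 1,
    scan_both_strands: bool | None = None,
    break_ties_by_abundance: bool = False,
) -> tuple[list[CellTagHit], ExtractionStats]:
    """Extract CellTags from reads and error-correct against an allowlist.

    ``scan_both_strands=None`` picks the per-read default: ON for ATAC
    (amplicons may be sequenced in either orientation), OFF for RNA
    (stranded 3' capture). With ``allowlist=None`` extraction is uncorrected
    and any pattern match is kept verbatim.
    """
    hits: list[CellTagHit] = []
    stats = ExtractionStats()
    for read in reads:
        stats.total += 1
        both = scan_both_strands
        if both is None:
            both = read.modality == ATAC
        observed = extract_barcode(read.read_sequence, pattern, scan_both_strands=both)
        if observed is None:
            stats.rejected_no_pattern += 1
            continue
        if allowlist is None:
            tag = observed
        else:
            tag = allowlist.correct(
                observed, max_hamming, break_ties_by_abundance=break_ties_by_abundance
            )
            if tag is None:
                # distinguish "nothing close" from "tie" for the QC report
                dmin_ambiguous = (
                    max_hamming > 0
                    and allowlist.correct(observed, max_hamming=0) is None
                    and _is_ambiguous(observed, allowlist, max_hamming)
                )
                if dmin_ambiguous:
                    stats.rejected_ambiguous += 1
                else:
                    stats.rejected_no_allowlist_match += 1
                continue
        stats.matched += 1
        hits.append(
            CellTagHit(
                cell_barcode=read.cell_barcode,
                umi=read.umi,
                celltag=tag,
                modality=read.modality,
                sample_id=read.sample_id,
            )
        )
    return hits, stats


def _is_ambiguous(observed: str, allowlist: Allowlist, max_hamming: int) -> bool:
    """True when >=2 allowlist entries tie at the minimum distance <= max_hamming."""
    import numpy as np

    from .allowlist import _BASE_CODE

    if not set(observed) <= _BASE_CODE.keys():
        return False
    obs = np.array([_BASE_CODE[c] for c in observed], dtype=np.uint8)
    dists = (allowlist._encoded != obs).sum(axis=1)
    dmin = int(dists.min())
    return dmin <= max_hamming and int((dists == dmin).sum()) >= 2


# ---------------------------------------------------------------------------
# I/O


def read_fastq(
    path: str | Path, modality: str = RNA, sample_id: str = "sample"
) -> Iterator[TaggedRead]:
    """Iterate TaggedReads from a FASTQ whose descriptions carry ``CB:..;UMI:..``.

    The UMI field is omitted (or empty) for ATAC reads.
    """
    for record in SeqIO.parse(str(path), "fastq"):
        fields = dict(
            part.split(":", 1) for part in record.description.split() [-1].split(";")
            if ":" in part
        )
        cb = fields.get("CB")
        if cb is None:
            raise ValueError(f"{path}: read {record.id} lacks a CB: field")
        umi = fields.get("UMI") or None
        yield TaggedRead(
            cell_barcode=cb,
            umi=umi if modality == RNA else None,
            read_sequence=str(record.seq).upper(),
            modality=modality,
            sample_id=sample_id,
        )


READS_TSV_COLUMNS = ["cell_barcode", "umi", "sequence", "modality", "sample_id"]


def read_reads_tsv(path: str | Path) -> Iterator[TaggedRead]:
    """Iterate TaggedReads from a TSV with the documented header."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(READS_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for row in df.itertuples(index=False):
        umi = row.umi or None
        yield TaggedRead(
            cell_barcode=row.cell_barcode,
            umi=umi,
            read_sequence=row.sequence,
            modality=row.modality,
            sample_id=row.sample_id,
        )


def write_reads_tsv(reads: Iterable[TaggedRead], path: str | Path) -> None:
    """Write TaggedReads as TSV (inverse of :func:`read_reads_tsv`)."""
    rows = [
        (r.cell_barcode, r.umi or "", r.read_sequence, r.modality, r.sample_id)
        for r in reads
    ]
    pd.DataFrame(rows, columns=READS_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def write_hits_tsv(hits: Iterable[CellTagHit], path: str | Path) -> None:
    """Write extracted hits as TSV: cell_barcode, umi, celltag, modality, sample_id."""
    rows = [
        (h.cell_barcode, h.umi or "", h.celltag, h.modality, h.sample_id) for h in hits
    ]
    pd.DataFrame(
        rows, columns=["cell_barcode", "umi", "celltag", "modality", "sample_id"]
    ).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list[CellTagHit]:
    """Read a hits TSV written by :func:`write_hits_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        CellTagHit(
            cell_barcode=row.cell_barcode,
            umi=row.umi or None,
            celltag=row.celltag,
            modality=row.modality,
            sample_id=row.sample_id,
        )
        for row in df.itertuples(index=False)
    ]
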