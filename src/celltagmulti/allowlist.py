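"""Allowlists of valid CellTag barcodes and Hamming-distance error correction.

The sequenced catalogue of barcodes actually present in a CellTag library
(~80,000 for the v1 CellTag-multi library) is used to reject artefactual
sequences and to snap sequencing errors in the random segment back to the
true barcode. Correction is conservative: an observed sequence is corrected
only when exactly one allowlist entry lies within ``max_hamming``
substitutions; ties are rejected by default (optionally broken toward the
most abundant entry), since a wrong correction merges unrelated clones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class BarcodeLengthError(ValueError):
    """Observed barcode length does not match the allowlist."""


@dataclass
class Allowlist:
    """A set of valid CellTag random-segment sequences with optional weights.

    Parameters
    ----------
    barcodes
        Unique sequences, all of one length (the pattern's random length).
    abundance
        Optional per-barcode weight (e.g. read counts from sequencing the
        plasmid library); used for weighted sampling and optional tie-breaks.
    """

    barcodes: list[str]
    abundance: np.ndarray | None = None
    _index: dict[str, int] = field(init=False, repr=False)
    _encoded: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("allowlist is empty")
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) != 1:
            raise ValueError(f"allowlist barcodes have mixed lengths: {sorted(lengths)}")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("allowlist barcodes are not unique")
        if self.abundance is not None:
            self.abundance = np.asarray(self.abundance, dtype=float)
            if len(self.abundance) != len(self.barcodes):
                raise ValueError("abundance length mismatch")
            if (self.abundance < 0).any() or self.abundance.sum() <= 0:
                raise ValueError("abundance weights must be >=0 with positive sum")
        self._index = {b: i for i, b in enumerate(self.barcodes)}
        # 2-bit-per-base uint8 matrix for vectorised Hamming scans
        code = np.zeros((len(self.barcodes), self.barcode_length), dtype=np.uint8)
        for i, b in enumerate(self.barcodes):
            code[i] = [_BASE_CODE[c] for c in b]
        self._encoded = code

    @property
    def barcode_length(self) -> int:
        return len(self.barcodes[0])

    def __len__(self) -> int:
        return len(self.barcodes)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._index

    def correct(
        self,
        observed: str,
        max_hamming: int = 1,
        break_ties_by_abundance: bool = False,
    ) -> str | None:
        """Snap ``observed`` to the unique allowlist entry within ``max_hamming``.

        Exact matches are returned at distance 0. Returns ``None`` when no
        entry is in range, or when two or more entries tie at the minimum
        distance (unless ``break_ties_by_abundance`` and weights are
        available, in which case the heaviest tied entry wins; remaining
        ties are still rejected).
        """
        if len(observed) != self.barcode_length:
            raise BarcodeLengthError(
                f"observed length {len(observed)} != allowlist length {self.barcode_length}"
            )
        hit = self._index.get(observed)
        if hit is not None:
            return observed
        if max_hamming <= 0 or not set(observed) <= _BASE_CODE.keys():
            return None
        obs = np.array([_BASE_CODE[c] for c in observed], dtype=np.uint8)
        dists = (self._encoded != obs).sum(axis=1)
        dmin = int(dists.min())
        if dmin > max_hamming:
            return None
        ties = np.flatnonzero(dists == dmin)
        if len(ties) == 1:
            return self.barcodes[int(ties[0])]
        if break_ties_by_abundance and self.abundance is not None:
            weights = self.abundance[ties]
            best = ties[weights == weights.max()]
            if len(best) == 1:
                return self.barcodes[int(best[0])]
        return None


def correct_barcode(
    observed: str,
    allowlist: Allowlist,
    max_hamming: int = 1,
    break_ties_by_abundance: bool = False,
) -> str | None:
    """Functional wrapper around :meth:`Allowlist.correct`."""
    return allowlist.correct(observed, max_hamming, break_ties_by_abundance)


def read_allowlist(path: str | Path) -> Allowlist:
    """Read an allowlist CSV with header ``barcode[,abundance]``."""
    df = pd.read_csv(path)
    if "barcode" not in df.columns:
        raise ValueError(f"{path}: allowlist CSV needs a 'barcode' column")
    abundance = df["abundance"].to_numpy() if "abundance" in df.columns else None
    return Allowlist(barcodes=df["barcode"].astype(str).tolist(), abundance=abundance)


def write_allowlist(allowlist: Allowlist, path: str | Path) -> None:
    """Write an allowlist CSV (inverse of :func:`read_allowlist`)."""
    data: dict[str, object] = {"barcode": allowlist.barcodes}
    if allowlist.abundance is not None:
        data["abundance"] = allowlist.abundance
    pd.DataFrame(data).to_csv(path, index=False)
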