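"""CellTag barcode patterns and extraction of random segments from reads.

A CellTag is a lentivirally delivered DNA barcode whose variable (random)
bases are interleaved with short fixed spacer sequences. Two library designs
are built in:

* ``v1`` — ``N3 GT N3 CT N3 AG N3 TG N3 CA N3`` (18 random bases, 28 total),
  the CellTag-multi library used for lineage tracing.
* ``v0`` — ``N5 GTA N5 CCT N5 ATC N5 GAT N5`` (25 random bases, 37 total),
  an earlier design used as the second library in species-mixing controls.

Extraction scans a read for the first position where every fixed spacer
matches exactly and returns the concatenated random bases. Sequencing errors
in the random bases are handled downstream by allowlist correction
(:mod:`celltagmulti.allowlist`); errors in a spacer cause the read to be
rejected, which keeps extraction unambiguous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class PatternSpecError(ValueError):
    """Raised when a pattern specification string cannot be parsed."""


@dataclass(frozen=True)
class BarcodePattern:
    """A CellTag barcode layout: alternating random runs and fixed spacers.

    Parameters
    ----------
    name
        Short identifier, e.g. ``"v1"``.
    segments
        Ordered ``("random", length)`` / ``("fixed", literal)`` tuples.
    """

    name: str
    segments: tuple[tuple[str, object], ...]
    _regex: re.Pattern = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.segments:
            raise PatternSpecError("pattern has no segments")
        parts = []
        n_random = 0
        for kind, value in self.segments:
            if kind == "random":
                if not isinstance(value, int) or value <= 0:
                    raise PatternSpecError(f"zero-length random segment: {value!r}")
                parts.append("([ACGT]{%d})" % value)
                n_random += 1
            elif kind == "fixed":
                if not value or not set(value) <= VALID_BASES:
                    raise PatternSpecError(f"invalid fixed segment: {value!r}")
                parts.append(re.escape(value))
            else:
                raise PatternSpecError(f"unknown segment kind: {kind!r}")
        if n_random == 0:
            raise PatternSpecError("pattern needs at least one random segment")
        object.__setattr__(self, "_regex", re.compile("".join(parts)))

    @property
    def random_length(self) -> int:
        """Total number of random bases."""
        return sum(v for k, v in self.segments if k == "random")

    @property
    def total_length(self) -> int:
        """Total pattern length in bases."""
        return sum(v if k == "random" else len(v) for k, v in self.segments)

    def embed(self, random_bases: str) -> str:
        """Build the full barcode sequence carrying ``random_bases``.

        The inverse of extraction: splices the given random bases into the
        pattern's layout. Used by the read simulator and in round-trip tests.
        """
        if len(random_bases) != self.random_length:
            raise ValueError(
                f"need {self.random_length} random bases, got {len(random_bases)}"
            )
        out = []
        i = 0
        for kind, value in self.segments:
            if kind == "random":
                out.append(random_bases[i : i + value])
                i += value
            else:
                out.append(value)
        return "".join(out)

    def search(self, sequence: str) -> str | None:
        """Leftmost match of the pattern in ``sequence``; concatenated random bases."""
        m = self._regex.search(sequence)
        if m is None:
            return None
        return "".join(m.groups())


def parse_pattern_spec(spec: str, name: str = "custom") -> BarcodePattern:
    """Parse a whitespace-separated pattern spec like ``"N3 GT N3 CT N3"``.

    Tokens are either ``N<k>`` (a run of *k* random bases) or a literal
    A/C/G/T string (a fixed spacer). Subscript-style specs from library
    descriptions, e.g. ``(N)_3GT(N)_3``, are normalised first.
    """
    normalised = re.sub(r"\(N\)_?(\d+)", r" N\1 ", spec)
    tokens = normalised.split()
    if not tokens:
        raise PatternSpecError("empty pattern spec")
    segments: list[tuple[str, object]] = []
    for tok in tokens:
        m = re.fullmatch(r"N(\d+)", tok)
        if m:
            length = int(m.group(1))
            if length == 0:
                raise PatternSpecError(f"zero-length segment: {tok!r}")
            segments.append(("random", length))
        elif set(tok) <= VALID_BASES:
            segments.append(("fixed", tok))
        else:
            raise PatternSpecError(f"illegal token: {tok!r}")
    return BarcodePattern(name=name, segments=tuple(segments))


#: Built-in library designs.
BUILTIN_PATTERNS: dict[str, BarcodePattern] = {
    "v1": parse_pattern_spec("N3 GT N3 CT N3 AG N3 TG N3 CA N3", name="v1"),
    "v0": parse_pattern_spec("N5 GTA N5 CCT N5 ATC N5 GAT N5", name="v0"),
}


def get_pattern(name_or_spec: str) -> BarcodePattern:
    """Look up a built-in pattern by name, or parse ``name_or_spec`` as a spec."""
    if name_or_spec in BUILTIN_PATTERNS:
        return BUILTIN_PATTERNS[name_or_spec]
    return parse_pattern_spec(name_or_spec)


def extract_barcode(
    read_sequence: str,
    pattern: BarcodePattern,
    scan_both_strands: bool = False,
) -> str | None:
    """Extract the random-segment bases of ``pattern`` from a read.

    Returns the concatenated random bases at the first position where all
    fixed spacers match exactly, or ``None`` if the read does not carry the
    pattern. The forward strand is searched before the reverse complement
    (only when ``scan_both_strands`` is set; ATAC-derived amplicons may be
    read in either orientation, 3'-capture RNA reads are stranded).

    Random segments containing ``N`` never match (an N cannot be
    distance-scored against an allowlist).
    """
    hit = pattern.search(read_sequence)
    if hit is None and scan_both_strands:
        hit = pattern.search(reverse_complement(read_sequence))
    return hit
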