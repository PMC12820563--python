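"""Sequence and interval primitives shared by every pipeline stage.

DNA strings are plain Python ``str`` over the IUPAC alphabet, normalized to
uppercase.  Degenerate codes (N, K, Y, H, ...) are first-class: they appear in
motif patterns, are complemented correctly by :func:`reverse_complement`, and
expand to per-position base sets in :func:`matches` and
:func:`scan_nonoverlapping`.

Genomic coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator

#: IUPAC degenerate code -> set of concrete bases it stands for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_ALPHABET = "ACGTRYSWKMBDHVN"
_COMPLEMENT = str.maketrans(_ALPHABET, "TGCAYRSWMKVHDBN")


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside the IUPAC alphabet."""


def normalize(s: str) -> str:
    """Uppercase ``s`` and reject characters outside the IUPAC alphabet.

    Lowercase input (soft-masked genome FASTA) is accepted and uppercased.
    """
    u = s.upper()
    for ch in u:
        if ch not in IUPAC_SETS:
            raise AlphabetError(f"unsupported character {ch!r} in sequence")
    return u


def reverse_complement(s: str) -> str:
    """Reverse-complement with correct handling of degenerate codes.

    N maps to N, K to M, Y to R, etc.  An involution:
    ``reverse_complement(reverse_complement(s)) == s``.
    """
    return normalize(s).translate(_COMPLEMENT)[::-1]


def matches(pattern: str, s: str) -> bool:
    """True iff each base of ``s`` lies in the base set of ``pattern`` there.

    ``pattern`` may use any IUPAC code; ``s`` is expected concrete
    ({A,C,G,T}).  Raises ``ValueError`` on length mismatch.
    """
    if len(pattern) != len(s):
        raise ValueError(
            f"pattern length {len(pattern)} != sequence length {len(s)}"
        )
    for p, c in zip(pattern, s):
        if c not in IUPAC_SETS[p]:
            return False
    return True


def pattern_to_regex(pattern: str) -> re.Pattern[str]:
    """Compile a degenerate pattern to a regex of per-position base classes.

    A concrete base compiles to itself; a degenerate code to a character
    class of the bases it stands for (N -> ``[ACGT]``, so an N in the scanned
    sequence never matches).
    """
    parts = []
    for ch in normalize(pattern):
        bases = IUPAC_SETS[ch]
        parts.append(ch if len(bases) == 1 else "[" + "".join(sorted(bases)) + "]")
    return re.compile("".join(parts))


def scan_nonoverlapping(pattern: str, s: str) -> list[int]:
    """Greedy left-to-right scan; after a match at ``i`` resume at ``i + len``.

    Matches of the *same* pattern never overlap; callers that scan several
    patterns over the same sequence may still see overlaps between different
    patterns.  Returns match start positions in increasing order.
    """
    return [m.start() for m in pattern_to_regex(pattern).finditer(s)]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def signed_border_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Signed border-to-border distance from ``a`` to ``b``.

    Positive when ``b`` lies downstream of ``a`` (``b.start - a.end``),
    negative when upstream (``-(a.start - b.end)``), and 0 when the two
    intervals overlap or abut.  Antisymmetric for disjoint intervals.
    """
    if a.chrom != b.chrom:
        raise ValueError(f"intervals on different chromosomes: {a.chrom} vs {b.chrom}")
    if b.start >= a.end:
        return b.start - a.end
    if b.end <= a.start:
        return -(a.start - b.end)
    return 0


def iter_kmers(k: int) -> Iterator[str]:
    """All 4**k concrete k-mers in lexicographic order (A < C < G < T)."""
    if k == 0:
        yield ""
        return
    for prefix in iter_kmers(k - 1):
        for b in "ACGT":
            yield prefix + b
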