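"""Genomic coordinate primitives, interval algebra and IUPAC motif scanning.

All coordinates inside the package are 1-based and fully inclusive, the
convention used by printed CNV/element tables (``width = end - start + 1``).
BED-family files (0-based, half-open) are converted at the I/O boundary in
:mod:`cfescan.io`, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval",
    "StrandedInterval",
    "MotifPattern",
    "SequenceRecord",
    "interval_width",
    "intervals_overlap",
    "iupac_scan",
    "reverse_complement",
    "IUPAC_CODES",
]

#: IUPAC nucleotide codes mapped to the set of concrete bases they admit.
#: ``U`` is an alias for ``T`` so RNA-alphabet motifs can be scanned over DNA.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
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

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (``N`` maps to ``N``)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully inclusive genomic interval.

    Invariants: ``start >= 1`` and ``end >= start``, so every constructible
    interval has a strictly positive width.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start}) on {self.chrom}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return intervals_overlap(self, other)

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    def __str__(self) -> str:  # e.g. "chr11:84430074-84432618"
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class StrandedInterval:
    """An interval with a strand, one of ``+`` or ``-``."""

    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __str__(self) -> str:
        return f"{self.interval}({self.strand})"


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate nucleotide motif over the IUPAC alphabet.

    The recursive-splicing screen uses ``YYYAGGURAG``; ``U`` is treated as
    ``T`` throughout.
    """

    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("motif pattern must be non-empty")
        bad = [c for c in self.pattern.upper() if c not in IUPAC_CODES]
        if bad:
            raise ValueError(f"illegal IUPAC code(s) {bad!r} in pattern {self.pattern!r}")

    def __len__(self) -> int:
        return len(self.pattern)

    def classes(self) -> list[frozenset[str]]:
        return [IUPAC_CODES[c] for c in self.pattern.upper()]


_SEQ_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over ``{A, C, G, T, N}``."""

    name: str
    seq: str = field(repr=False)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("sequence record needs a non-empty name")
        seq = self.seq.upper()
        if set(seq) - _SEQ_ALPHABET:
            bad = sorted(set(seq) - _SEQ_ALPHABET)
            raise ValueError(f"illegal sequence characters {bad!r} in record {self.name!r}")
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)

    def subseq(self, start: int, end: int) -> str:
        """1-based inclusive slice; errors if outside the sequence."""
        if start < 1 or end > len(self.seq) or end < start:
            raise ValueError(
                f"subsequence {start}-{end} outside record {self.name!r} (len {len(self.seq)})"
            )
        return self.seq[start - 1 : end]


def interval_width(iv: GenomicInterval) -> int:
    """Width of a 1-based inclusive interval: ``end - start + 1``."""
    return iv.width


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` and ``b`` are on the same chromosome and share >= 1 base.

    Bookended (abutting) intervals do not overlap.
    """
    return a.chrom == b.chrom and a.start <= b.end and b.start <= a.end


def _base_matches(base: str, cls: frozenset[str]) -> bool:
    # an ambiguous base only satisfies the fully degenerate class (pattern N)
    if base == "N":
        return len(cls) == 4
    return base in cls


def _scan_forward(seq: str, classes: list[frozenset[str]]) -> list[int]:
    w = len(classes)
    hits = []
    for i in range(len(seq) - w + 1):
        if all(_base_matches(seq[i + j], classes[j]) for j in range(w)):
            hits.append(i + 1)
    return hits


def iupac_scan(
    seq: SequenceRecord, pattern: MotifPattern, strand_mode: str = "given"
) -> list[int]:
    """All 1-based start positions where ``pattern`` matches ``seq``.

    ``strand_mode='given'`` scans the forward sequence only.
    ``strand_mode='both'`` additionally scans the reverse complement and
    reports those matches against forward coordinates (the position of the
    left-most base of the matching window on the forward strand). Positions
    are returned sorted, without duplicates.

    An ``N`` in the sequence matches only the ``N`` pattern class (an
    ambiguous base is not evidence for a motif).
    """
    if strand_mode not in ("given", "both"):
        raise ValueError(f"strand_mode must be 'given' or 'both', got {strand_mode!r}")
    classes = pattern.classes()
    s = seq.seq
    hits = set(_scan_forward(s, classes))
    if strand_mode == "both":
        w = len(classes)
        rc = reverse_complement(s)
        for p in _scan_forward(rc, classes):
            # match starting at p (1-based) on the reverse complement occupies
            # forward bases [len - p - w + 2, len - p + 1]
            hits.add(len(s) - p - w + 2)
    return sorted(hits)
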