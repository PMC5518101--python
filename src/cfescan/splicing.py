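"""First-exon 3' boundary detection from per-base coverage differentials.

A donor splice site at the 3' end of an expressed first exon leaves an
abrupt drop in per-base RNA-seq depth between the last exonic base and the
first intronic base (reading 5'->3' on the gene strand). The caller scans a
candidate region for such steps, validates the AG|GT donor consensus in the
genomic sequence, and requires junction support: no reads splicing INTO the
region (a first exon has no upstream acceptor) and at least one read
splitting from the detected donor into a downstream annotated exon.

Boundary convention: a step lives between two adjacent bases; ``pos`` is
always the lower (left, forward-strand) base of that pair, mirroring the
two-base notation of printed splice sites. On the plus strand ``pos`` is the
last exonic base; on the minus strand the last exonic base (in gene
orientation) is ``pos + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .intervals import (
    GenomicInterval,
    MotifPattern,
    SequenceRecord,
    iupac_scan,
    reverse_complement,
)

__all__ = [
    "DONOR_CONSENSUS",
    "RECURSIVE_EXON_MOTIF",
    "CoverageTrack",
    "CoverageStep",
    "DonorSite",
    "JunctionRecord",
    "CfeCall",
    "scan_coverage_steps",
    "donor_consensus_check",
    "call_first_exon",
    "recursive_motif_absent",
    "last_exonic_pos",
]

#: donor context: two exonic bases then two intronic bases, gene-strand orientation
DONOR_CONSENSUS = "AGGT"

#: juxtaposed acceptor/donor element marking recursive (stepwise) intron removal
RECURSIVE_EXON_MOTIF = MotifPattern("YYYAGGURAG")


@dataclass(frozen=True)
class CoverageTrack:
    """Per-base read depth for one chromosome segment.

    ``origin`` is the 1-based genomic position of ``depth[0]``.
    """

    chrom: str
    origin: int
    depth: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth, dtype=np.int64)
        if depth.ndim != 1 or depth.size < 1:
            raise ValueError("depth must be a non-empty 1-D vector")
        if (depth < 0).any():
            raise ValueError("depth values must be >= 0")
        if self.origin < 1:
            raise ValueError("origin must be >= 1 (1-based coordinates)")
        object.__setattr__(self, "depth", depth)

    @property
    def extent(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.origin, self.origin + len(self.depth) - 1)

    def depth_at(self, pos: int) -> int:
        if not self.extent.contains_pos(pos):
            raise ValueError(f"position {pos} outside track extent {self.extent}")
        return int(self.depth[pos - self.origin])


@dataclass(frozen=True)
class CoverageStep:
    """An abrupt depth change between adjacent bases ``pos`` and ``pos + 1``.

    ``delta`` is the positive drop magnitude in the gene 5'->3' direction.
    """

    pos: int
    delta: int

    def __post_init__(self) -> None:
        if self.delta < 1:
            raise ValueError("step delta must be >= 1")

    def notation(self) -> str:
        """The printed two-base form, e.g. ``84431338-9``."""
        lo, hi = str(self.pos), str(self.pos + 1)
        for i, (a, b) in enumerate(zip(lo, hi)):
            if a != b:
                return f"{lo}-{hi[i:]}"
        return f"{lo}-{hi}"


def last_exonic_pos(step: CoverageStep, strand: str) -> int:
    """Last exonic base in gene orientation for a donor-side step."""
    if strand == "+":
        return step.pos
    if strand == "-":
        return step.pos + 1
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


@dataclass(frozen=True)
class DonorSite:
    """A candidate donor boundary with its 4-nt genomic context (2 exonic + 2 intronic)."""

    boundary: CoverageStep
    strand: str
    context: str
    passes: bool

    def __post_init__(self) -> None:
        if len(self.context) != 4:
            raise ValueError("donor context must be exactly 4 nt")


@dataclass(frozen=True)
class JunctionRecord:
    """One split-read junction: donor base -> acceptor base with read support."""

    chrom: str
    donor_pos: int
    acceptor_pos: int
    read_count: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.donor_pos == self.acceptor_pos:
            raise ValueError("junction donor and acceptor coincide")
        if self.read_count < 1:
            raise ValueError("junction read_count must be >= 1")


def scan_coverage_steps(
    track: CoverageTrack,
    region: GenomicInterval,
    min_delta: int = 20,
    strand: str = "+",
) -> list[CoverageStep]:
    """All donor-side steps of magnitude >= ``min_delta`` within ``region``.

    Only drops in the gene 5'->3' direction qualify (donor candidates): on
    the plus strand a step down from ``pos`` to ``pos + 1``; on the minus
    strand a step up in forward coordinates. The last exonic base of each
    reported step lies inside ``region``; results are sorted by position.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if region.chrom != track.chrom or not track.extent.contains(region):
        raise ValueError(f"region {region} outside track extent {track.extent}")
    depth = track.depth
    lo = region.start - track.origin
    hi = region.end - track.origin  # inclusive index of region end
    steps: list[CoverageStep] = []
    if strand == "+":
        # pair (p, p+1), last exonic base p in region; p+1 may extend past the
        # region edge but must be inside the track
        stop = min(hi, len(depth) - 2)
        for i in range(lo, stop + 1):
            d = int(depth[i]) - int(depth[i + 1])
            if d >= min_delta:
                steps.append(CoverageStep(pos=track.origin + i, delta=d))
    else:
        # pair (p, p+1), last exonic base p+1 in region; p may lie one base
        # left of the region edge
        start = max(lo - 1, 0)
        stop = min(hi - 1, len(depth) - 2)
        for i in range(start, stop + 1):
            d = int(depth[i + 1]) - int(depth[i])
            if d >= min_delta:
                steps.append(CoverageStep(pos=track.origin + i, delta=d))
    return steps


def donor_consensus_check(
    genome: SequenceRecord, boundary: CoverageStep, strand: str = "+"
) -> DonorSite:
    """Extract the 4-nt donor context at a step and test it against AG|GT.

    The window covers the two bases on each side of the boundary, i.e.
    forward positions ``pos-1 .. pos+2``; on the minus strand the window is
    reverse complemented so the context always reads exon(2) then intron(2)
    in gene orientation.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    pos = boundary.pos
    if pos - 1 < 1 or pos + 2 > len(genome):
        raise ValueError(
            f"boundary {pos} too close to the edge of sequence {genome.name!r}"
        )
    window = genome.subseq(pos - 1, pos + 2)
    context = window if strand == "+" else reverse_complement(window)
    return DonorSite(
        boundary=boundary, strand=strand, context=context, passes=context == DONOR_CONSENSUS
    )


@dataclass(frozen=True)
class CfeCall:
    """A called coding-first-exon 3' boundary with its supporting evidence."""

    region: GenomicInterval
    strand: str
    donor: DonorSite
    junction: JunctionRecord
    acceptor_exon: GenomicInterval

    @property
    def coding_end(self) -> int:
        """Last exonic base of the first exon, gene orientation."""
        return last_exonic_pos(self.donor.boundary, self.strand)


def call_first_exon(
    region: GenomicInterval,
    steps: Sequence[CoverageStep],
    junctions: Sequence[JunctionRecord],
    exons: Sequence[GenomicInterval],
    genome: SequenceRecord,
    strand: str = "+",
) -> CfeCall | None:
    """Call a first-exon 3' boundary in ``region``, or ``None``.

    Requires, in order: (a) at least one step whose donor context matches
    AG|GT; (b) no junction acceptor inside the region (nothing splices into a
    first exon); (c) a junction whose donor coincides exactly with the chosen
    boundary and whose acceptor falls in a downstream annotated exon. Among
    steps passing (a) the largest delta wins, ties going to the most
    downstream position in gene orientation (the longest supported exon).
    """
    checked = [donor_consensus_check(genome, s, strand) for s in steps]
    passing = [d for d in checked if d.passes]
    if not passing:
        return None

    for j in junctions:
        if j.chrom == region.chrom and region.contains_pos(j.acceptor_pos):
            return None

    downstream_rank = (lambda d: d.boundary.pos) if strand == "+" else (lambda d: -d.boundary.pos)
    chosen = max(passing, key=lambda d: (d.boundary.delta, downstream_rank(d)))
    donor_base = last_exonic_pos(chosen.boundary, strand)

    for j in sorted(junctions, key=lambda j: -j.read_count):
        if j.chrom != region.chrom or j.donor_pos != donor_base:
            continue
        for exon in exons:
            if not exon.contains_pos(j.acceptor_pos):
                continue
            is_downstream = exon.start > donor_base if strand == "+" else exon.end < donor_base
            if is_downstream:
                return CfeCall(
                    region=region,
                    strand=strand,
                    donor=chosen,
                    junction=j,
                    acceptor_exon=exon,
                )
    return None


def recursive_motif_absent(
    genome: SequenceRecord, cfe_region: GenomicInterval | None, strand: str = "+"
) -> bool:
    """True iff the recursive exon motif YYYAGGURAG is absent from the region.

    The scan runs on the gene strand. An empty/too-short region is vacuously
    motif-free.
    """
    if cfe_region is None or cfe_region.width < len(RECURSIVE_EXON_MOTIF):
        return True
    seq = genome.subseq(cfe_region.start, cfe_region.end)
    if strand == "-":
        seq = reverse_complement(seq)
    rec = SequenceRecord(name=f"{cfe_region}", seq=seq)
    return not iupac_scan(rec, RECURSIVE_EXON_MOTIF, strand_mode="given")
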