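"""Smallest regions of overlap (SROs) from deletion stacks.

An SRO is a maximal genome segment over which the set of overlapping
deletions is constant. Partitioning the union of deletion footprints at
every deletion breakpoint (start and end+1) yields disjoint, sorted SROs
whose union equals the deletion footprint; segments covered by no deletion
are dropped. Adjacent SROs passing a case-count threshold are merged into
aggregated regions for reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .cohort import CnvRecord, DELETION
from .intervals import GenomicInterval

__all__ = ["SRO", "AggregatedRegion", "build_sros", "aggregate_adjacent", "sros_to_bed_rows"]


@dataclass(frozen=True)
class SRO:
    """An atomic segment with a constant overlapping-deletion set.

    ``patient_ids`` are the contributing case patients; ``control_patient_ids``
    holds the same per control cohort. Counts are distinct patients.
    """

    interval: GenomicInterval
    patient_ids: frozenset[str]
    control_patient_ids: Mapping[str, frozenset[str]] = field(default_factory=dict)

    @property
    def case_count(self) -> int:
        return len(self.patient_ids)

    @property
    def control_counts(self) -> dict[str, int]:
        return {name: len(ids) for name, ids in self.control_patient_ids.items()}

    @property
    def total_count(self) -> int:
        return self.case_count + sum(self.control_counts.values())


@dataclass(frozen=True)
class AggregatedRegion:
    """A maximal run of genomically adjacent SROs meeting a case threshold."""

    interval: GenomicInterval
    member_sros: tuple[SRO, ...]

    def __post_init__(self) -> None:
        if not self.member_sros:
            raise ValueError("aggregated region needs >= 1 member SRO")
        for a, b in zip(self.member_sros, self.member_sros[1:]):
            if b.interval.start != a.interval.end + 1:
                raise ValueError(
                    f"member SROs not adjacent: {a.interval} then {b.interval}"
                )

    @property
    def case_patient_ids(self) -> frozenset[str]:
        ids: set[str] = set()
        for s in self.member_sros:
            ids |= s.patient_ids
        return frozenset(ids)


def build_sros(
    deletions: Sequence[CnvRecord], case_cohorts: frozenset[str] | set[str] = frozenset({"case"})
) -> list[SRO]:
    """Partition a one-chromosome deletion stack into SROs.

    All records must be deletions on a single chromosome (partition by
    chromosome upstream). Breakpoints are taken from every input record, so
    the constant-deletion-set invariant holds for all cohorts on the shared
    partition; per-cohort counts are then read off each segment. The result
    is independent of input order.
    """
    if not deletions:
        return []
    chroms = {d.interval.chrom for d in deletions}
    if len(chroms) > 1:
        raise ValueError(f"deletions span several chromosomes: {sorted(chroms)}")
    bad = [d.patient_id for d in deletions if d.state != DELETION]
    if bad:
        raise ValueError(f"non-deletion records in SRO input: {bad}")
    chrom = chroms.pop()

    breakpoints = sorted({d.interval.start for d in deletions} | {d.interval.end + 1 for d in deletions})
    tree = IntervalTree()
    for d in deletions:
        tree.addi(d.interval.start, d.interval.end + 1, d)  # half-open for the tree
    out: list[SRO] = []
    for lo, hi_excl in zip(breakpoints, breakpoints[1:]):
        seg = GenomicInterval(chrom, lo, hi_excl - 1)
        covering = [hit.data for hit in tree.overlap(lo, hi_excl)]
        if not covering:
            continue
        case_ids = frozenset(
            d.patient_id for d in covering if d.cohort in case_cohorts
        )
        controls: dict[str, set[str]] = {}
        for d in covering:
            if d.cohort not in case_cohorts:
                controls.setdefault(d.cohort, set()).add(d.patient_id)
        out.append(
            SRO(
                interval=seg,
                patient_ids=case_ids,
                control_patient_ids={k: frozenset(v) for k, v in controls.items()},
            )
        )
    return out


def aggregate_adjacent(sros: Sequence[SRO], min_case: int = 1) -> list[AggregatedRegion]:
    """Merge maximal runs of bookended SROs with ``case_count >= min_case``.

    A gap of even one base, or an SRO below the threshold, breaks a run.
    """
    if min_case < 1:
        raise ValueError("min_case must be >= 1")
    regions: list[AggregatedRegion] = []
    run: list[SRO] = []

    def flush() -> None:
        if run:
            iv = GenomicInterval(
                run[0].interval.chrom, run[0].interval.start, run[-1].interval.end
            )
            regions.append(AggregatedRegion(interval=iv, member_sros=tuple(run)))
            run.clear()

    for sro in sros:
        if sro.case_count < min_case:
            flush()
            continue
        if run and sro.interval.start != run[-1].interval.end + 1:
            flush()
        run.append(sro)
    flush()
    return regions


def sros_to_bed_rows(sros: Sequence[SRO]) -> list[str]:
    """BED6+2-style rows: interval, name, case_count, then per-cohort counts as JSON."""
    rows = []
    for i, s in enumerate(sros):
        iv = s.interval
        controls = json.dumps(s.control_counts, sort_keys=True)
        rows.append(
            f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\tSRO{i}\t{s.case_count}\t.\t"
            f"{s.case_count}\t{controls}"
        )
    return rows
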