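"""CNV cohort preprocessing: filtering, state categorisation, feature annotation.

The filtering rules are the common preprocessing applied to every cohort:
keep aberrations of 50 bp to 3 Mbp, and, when an array log2 ratio is
available, require |log2ratio| >= 0.32. Categorical sources (population SV
databases, literature reports) carry no ratio and face only the length rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval, intervals_overlap

__all__ = [
    "DELETION",
    "DUPLICATION",
    "MIN_CNV_BP",
    "MAX_CNV_BP",
    "MIN_ABS_LOG2RATIO",
    "CnvRecord",
    "FeatureSet",
    "categorize_state",
    "filter_cnvs",
    "annotate_deleted_features",
    "count_overlapping",
    "patients_overlapping",
]

DELETION = "deletion"
DUPLICATION = "duplication"

MIN_CNV_BP = 50
MAX_CNV_BP = 3_000_000
MIN_ABS_LOG2RATIO = 0.32

#: neurodevelopmental phenotype codes carried on case records
PHENOTYPE_CODES = ("C", "B", "P", "E", "other", "unknown")


def categorize_state(log2ratio: float) -> str:
    """Sign-based copy-state call: positive ratio -> duplication, negative -> deletion.

    A ratio of exactly 0 is uninterpretable and rejected.
    """
    if log2ratio > 0:
        return DUPLICATION
    if log2ratio < 0:
        return DELETION
    raise ValueError("log2ratio of 0 is neither a gain nor a loss; ambiguous record")


@dataclass(frozen=True)
class CnvRecord:
    """One patient aberration.

    ``cohort`` is the cohort name; which names are case cohorts is decided by
    the caller (conventionally ``"case"`` or a name listed in a pipeline
    config). ``state`` is derived from ``log2ratio`` when absent, and must be
    sign-consistent when both are given.
    """

    patient_id: str
    interval: GenomicInterval
    log2ratio: float | None = None
    state: str | None = None
    cohort: str = "case"
    inheritance: str | None = None
    phenotype: str | None = None

    def __post_init__(self) -> None:
        state = self.state
        if state is None:
            if self.log2ratio is None:
                raise ValueError(
                    f"record {self.patient_id}: need a state or a log2ratio"
                )
            state = categorize_state(self.log2ratio)
            object.__setattr__(self, "state", state)
        if state not in (DELETION, DUPLICATION):
            raise ValueError(f"record {self.patient_id}: unknown state {state!r}")
        if self.log2ratio is not None and self.log2ratio != 0:
            if categorize_state(self.log2ratio) != state:
                raise ValueError(
                    f"record {self.patient_id}: state {state!r} inconsistent with "
                    f"log2ratio {self.log2ratio}"
                )

    @property
    def is_deletion(self) -> bool:
        return self.state == DELETION

    def phenotype_flags(self) -> frozenset[str]:
        """Parse the phenotype string into its category codes (reporting aid)."""
        if not self.phenotype:
            return frozenset()
        return frozenset(p.strip() for p in self.phenotype.split(",") if p.strip())


def filter_cnvs(records: Sequence[CnvRecord]) -> list[CnvRecord]:
    """Apply the common preprocessing filter, preserving input order.

    Keeps records with 50 <= width <= 3,000,000 and, when a log2 ratio is
    present, |log2ratio| >= 0.32. Idempotent.
    """
    out = []
    for r in records:
        if not (MIN_CNV_BP <= r.interval.width <= MAX_CNV_BP):
            continue
        if r.log2ratio is not None and abs(r.log2ratio) < MIN_ABS_LOG2RATIO:
            continue
        out.append(r)
    return out


class FeatureSet:
    """Named genomic features (exons, candidate promoter regions, ...)."""

    def __init__(self, features: Mapping[str, GenomicInterval]):
        self._features = dict(features)

    def __getitem__(self, name: str) -> GenomicInterval:
        return self._features[name]

    def __contains__(self, name: str) -> bool:
        return name in self._features

    def __len__(self) -> int:
        return len(self._features)

    def items(self) -> Iterable[tuple[str, GenomicInterval]]:
        return self._features.items()

    def names(self) -> list[str]:
        return list(self._features)


def annotate_deleted_features(cnv: CnvRecord, features: FeatureSet) -> list[str]:
    """Names of all features overlapped by a deletion, sorted by genomic position."""
    if not cnv.is_deletion:
        raise ValueError(f"record {cnv.patient_id} is not a deletion")
    hits = [
        (iv.chrom, iv.start, iv.end, name)
        for name, iv in features.items()
        if intervals_overlap(cnv.interval, iv)
    ]
    return [name for *_pos, name in sorted(hits)]


def patients_overlapping(
    cohort: Sequence[CnvRecord],
    regions: GenomicInterval | Sequence[GenomicInterval],
    state: str = DELETION,
    mode: str = "any",
) -> set[str]:
    """Distinct patient ids with a CNV of ``state`` overlapping the region(s).

    ``mode='any'`` counts a patient overlapping at least one region;
    ``mode='all'`` requires every region to be hit (possibly by different
    CNVs of the same patient).
    """
    if isinstance(regions, GenomicInterval):
        regions = [regions]
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    hit_regions: dict[str, set[int]] = {}
    for rec in cohort:
        if rec.state != state:
            continue
        for i, region in enumerate(regions):
            if intervals_overlap(rec.interval, region):
                hit_regions.setdefault(rec.patient_id, set()).add(i)
    need = len(regions) if mode == "all" else 1
    return {pid for pid, hits in hit_regions.items() if len(hits) >= need}


def count_overlapping(
    cohort: Sequence[CnvRecord],
    regions: GenomicInterval | Sequence[GenomicInterval],
    state: str = DELETION,
    mode: str = "any",
) -> int:
    """Number of distinct patients with a CNV of ``state`` overlapping the region(s).

    The counting unit is the patient: a patient with several qualifying CNVs
    counts once.
    """
    return len(patients_overlapping(cohort, regions, state=state, mode=mode))
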