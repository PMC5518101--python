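"""Knowledge-driven promoter candidate evaluation.

A candidate is an H3K4me3 peak region overlapping at least one deletion SRO.
It passes the filter when it is deleted in >= 1 case patient, shows both
transcription-factor binding sites and CAGE peaks, has an H3K4me3/H3K4me1
peak-signal ratio strictly greater than 1, and contains at least one abrupt
coverage drop of the configured magnitude (default 20). Marker-context
classification (promoter-like / activated / repressed / quiescent) follows
the usual histone-code grouping: H3K4me3 marks promoter potential; H3K9ac,
H3K27ac and H3K4me1 act as genic activators; H3K27me3 and H3K9me3 as genic
repressors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .intervals import GenomicInterval, StrandedInterval, intervals_overlap
from .splicing import CoverageStep, DonorSite
from .sro import SRO

__all__ = [
    "PeakRecord",
    "MarkerGroups",
    "CagePeak",
    "BrainSpecificity",
    "CandidateRegion",
    "me3_me1_ratio",
    "classify_marker_context",
    "evaluate_candidate",
    "brain_specificity",
    "MIN_DELTA_DEFAULT",
]

#: abrupt-coverage threshold used by the candidate filter
MIN_DELTA_DEFAULT = 20


@dataclass(frozen=True)
class PeakRecord:
    """One called ChIP-seq peak (MACS-style narrow peak)."""

    interval: GenomicInterval
    marker: str
    tissue: str
    signal: float
    neglog10p: float = 0.0

    def __post_init__(self) -> None:
        for name, v in (("signal", self.signal), ("neglog10p", self.neglog10p)):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"peak {name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class MarkerGroups:
    """Histone-mark grouping used for context classification."""

    promoter: frozenset[str] = frozenset({"H3K4me3"})
    activators: frozenset[str] = frozenset({"H3K9ac", "H3K27ac", "H3K4me1"})
    repressors: frozenset[str] = frozenset({"H3K27me3", "H3K9me3"})

    def __post_init__(self) -> None:
        if (
            self.promoter & self.activators
            or self.promoter & self.repressors
            or self.activators & self.repressors
        ):
            raise ValueError("marker groups must be disjoint")


@dataclass(frozen=True)
class CagePeak:
    """A CAGE TSS peak with per-tissue expression (tags per million)."""

    interval: GenomicInterval
    strand: str
    expression: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = {t: v for t, v in self.expression.items() if v < 0}
        if bad:
            raise ValueError(f"negative TPM values: {bad}")


@dataclass(frozen=True)
class BrainSpecificity:
    brain_max: float
    other_max: float
    brain_specific: bool
    indeterminate: bool = False


def _overlapping_peaks(
    region: GenomicInterval, peaks: Sequence[PeakRecord], markers: frozenset[str] | set[str], tissue: str | None
) -> list[PeakRecord]:
    return [
        p
        for p in peaks
        if p.marker in markers
        and (tissue is None or p.tissue == tissue)
        and intervals_overlap(region, p.interval)
    ]


def me3_me1_ratio(
    region: GenomicInterval,
    peaks: Sequence[PeakRecord],
    tissue: str | None = None,
    statistic: str = "max_signal",
) -> float:
    """H3K4me3 / H3K4me1 peak ratio over ``region`` in one tissue.

    The default statistic compares the maximum overlapping peak signal of
    each mark (``statistic='max_neglog10p'`` uses the -log10 p column
    instead). No H3K4me3 peak -> 0 (fails the > 1 criterion); H3K4me3
    present but no H3K4me1 -> +inf (absence of the enhancer-leaning mark is
    taken as the strongest promoter evidence).
    """
    if statistic == "max_signal":
        value = lambda p: p.signal
    elif statistic == "max_neglog10p":
        value = lambda p: p.neglog10p
    else:
        raise ValueError(f"unknown ratio statistic {statistic!r}")
    me3 = _overlapping_peaks(region, peaks, {"H3K4me3"}, tissue)
    me1 = _overlapping_peaks(region, peaks, {"H3K4me1"}, tissue)
    if not me3:
        return 0.0
    top3 = max(value(p) for p in me3)
    if not me1 or max(value(p) for p in me1) == 0:
        return math.inf
    return top3 / max(value(p) for p in me1)


def classify_marker_context(
    region: GenomicInterval,
    peaks: Sequence[PeakRecord],
    groups: MarkerGroups = MarkerGroups(),
    tissue: str | None = None,
) -> str:
    """Classify a region by the strongest-claim mark present.

    Precedence promoter > activator > repressor; nothing overlapping ->
    ``quiescent``. A reporting aid, not a filter criterion.
    """
    if _overlapping_peaks(region, peaks, groups.promoter, tissue):
        return "promoter-like"
    if _overlapping_peaks(region, peaks, groups.activators, tissue):
        return "activated"
    if _overlapping_peaks(region, peaks, groups.repressors, tissue):
        return "repressed"
    return "quiescent"


def brain_specificity(cage: CagePeak, brain_tissues: set[str] | frozenset[str]) -> BrainSpecificity:
    """Compare a CAGE peak's expression in brain versus all other tissues.

    ``brain_specific`` requires a strictly higher brain maximum (ties
    resolve to False). When none of the named brain tissues appear in the
    expression map the comparison is flagged indeterminate.
    """
    if not cage.expression:
        raise ValueError("CAGE peak has an empty expression map")
    brain = [v for t, v in cage.expression.items() if t in brain_tissues]
    other = [v for t, v in cage.expression.items() if t not in brain_tissues]
    if not brain:
        return BrainSpecificity(
            brain_max=0.0,
            other_max=max(other) if other else 0.0,
            brain_specific=False,
            indeterminate=True,
        )
    brain_max = max(brain)
    other_max = max(other) if other else 0.0
    return BrainSpecificity(brain_max, other_max, brain_specific=brain_max > other_max)


@dataclass(frozen=True)
class CandidateRegion:
    """An evaluated H3K4me3 peak region with its criterion flags.

    ``passes_filter`` is exactly the conjunction: deleted in >= 1 case
    patient, TFBS present, CAGE present, me3/me1 ratio > 1, and >= 1 abrupt
    coverage step.
    """

    region: StrandedInterval
    host_gene: str = ""
    host_intron: str = ""
    deleted_in_cases: int = 0
    deleted_in_controls: Mapping[str, int] = field(default_factory=dict)
    case_patient_ids: frozenset[str] = frozenset()
    tfbs_present: bool = False
    cage_present: bool = False
    me3_me1_ratio: float = 0.0
    delta_sites: tuple[CoverageStep, ...] = ()
    splice_site: DonorSite | None = None
    annotation_type: str = "N"

    def __post_init__(self) -> None:
        if self.annotation_type not in ("P", "E", "N"):
            raise ValueError(f"annotation_type must be P, E or N, got {self.annotation_type!r}")
        if self.deleted_in_cases < 0:
            raise ValueError("deleted_in_cases must be >= 0")

    @property
    def passes_filter(self) -> bool:
        return (
            self.deleted_in_cases >= 1
            and self.tfbs_present
            and self.cage_present
            and self.me3_me1_ratio > 1
            and len(self.delta_sites) >= 1
        )


def evaluate_candidate(
    region: StrandedInterval,
    sros: Sequence[SRO],
    tfbs: Sequence[GenomicInterval],
    cage: Sequence[CagePeak],
    me3_me1: float,
    delta_sites: Sequence[CoverageStep],
    *,
    splice_site: DonorSite | None = None,
    host_gene: str = "",
    host_intron: str = "",
    annotation_type: str = "N",
) -> CandidateRegion:
    """Fill the criterion flags for one H3K4me3 peak region.

    ``deleted_in_cases`` counts distinct case patients contributing to SROs
    that overlap the region; control counts are per-cohort distinct patients
    from the same SRO partition. TFBS/CAGE presence means >= 1 record
    overlapping by >= 1 base (no score threshold).
    """
    iv = region.interval
    case_ids: set[str] = set()
    control_ids: dict[str, set[str]] = {}
    for s in sros:
        if not intervals_overlap(iv, s.interval):
            continue
        case_ids |= s.patient_ids
        for cohort, ids in s.control_patient_ids.items():
            control_ids.setdefault(cohort, set()).update(ids)
    return CandidateRegion(
        region=region,
        host_gene=host_gene,
        host_intron=host_intron,
        deleted_in_cases=len(case_ids),
        deleted_in_controls={k: len(v) for k, v in control_ids.items()},
        case_patient_ids=frozenset(case_ids),
        tfbs_present=any(intervals_overlap(iv, t) for t in tfbs),
        cage_present=any(intervals_overlap(iv, c.interval) for c in cage),
        me3_me1_ratio=me3_me1,
        delta_sites=tuple(delta_sites),
        splice_site=splice_site,
        annotation_type=annotation_type,
    )
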