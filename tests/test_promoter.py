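"""The four-criterion promoter filter and histone-context classification."""

import dataclasses
import math

import pytest

from cfescan.intervals import GenomicInterval, StrandedInterval
from cfescan.promoter import (
    BrainSpecificity,
    CagePeak,
    CandidateRegion,
    MarkerGroups,
    PeakRecord,
    brain_specificity,
    classify_marker_context,
    evaluate_candidate,
    me3_me1_ratio,
)
from cfescan.splicing import CoverageStep
from cfescan.sro import SRO

REGION = GenomicInterval("chrS", 1000, 2000)


def peak(marker, signal, start=1100, end=1900, tissue="fetal_brain"):
    return PeakRecord(GenomicInterval("chrS", start, end), marker, tissue, signal, signal * 1.5)


class TestMe3Me1Ratio:
    def test_ratio_of_max_signals(self):
        peaks = [peak("H3K4me3", 10.0), peak("H3K4me3", 6.0), peak("H3K4me1", 4.0)]
        assert me3_me1_ratio(REGION, peaks) == pytest.approx(2.5)

    def test_equal_signals_fail_strict_threshold(self):
        peaks = [peak("H3K4me3", 4.0), peak("H3K4me1", 4.0)]
        assert me3_me1_ratio(REGION, peaks) == pytest.approx(1.0)  # not > 1

    def test_absent_me1_gives_infinity(self):
        assert me3_me1_ratio(REGION, [peak("H3K4me3", 4.0)]) == math.inf

    def test_absent_me3_gives_zero(self):
        assert me3_me1_ratio(REGION, [peak("H3K4me1", 4.0)]) == 0.0

    def test_non_overlapping_and_other_tissue_peaks_ignored(self):
        peaks = [
            peak("H3K4me3", 50.0, start=5000, end=6000),  # outside region
            peak("H3K4me3", 9.0, tissue="liver"),
            peak("H3K4me3", 3.0),
            peak("H3K4me1", 2.0),
        ]
        assert me3_me1_ratio(REGION, peaks, tissue="fetal_brain") == pytest.approx(1.5)

    def test_scale_equivariance(self):
        peaks = [peak("H3K4me3", 10.0), peak("H3K4me1", 4.0)]
        scaled = [dataclasses.replace(p, signal=p.signal * 7.3) for p in peaks]
        assert me3_me1_ratio(REGION, scaled) == pytest.approx(me3_me1_ratio(REGION, peaks))


class TestMarkerContext:
    def test_promoter_marker_takes_precedence(self):
        peaks = [peak("H3K4me3", 5.0), peak("H3K27ac", 9.0)]
        assert classify_marker_context(REGION, peaks) == "promoter-like"

    def test_repressor_only(self):
        assert classify_marker_context(REGION, [peak("H3K27me3", 5.0)]) == "repressed"

    def test_activator_before_repressor(self):
        peaks = [peak("H3K4me1", 5.0), peak("H3K9me3", 9.0)]
        assert classify_marker_context(REGION, peaks) == "activated"

    def test_no_peaks_is_quiescent(self):
        assert classify_marker_context(REGION, []) == "quiescent"

    def test_groups_must_be_disjoint(self):
        with pytest.raises(ValueError):
            MarkerGroups(promoter=frozenset({"H3K4me3"}), activators=frozenset({"H3K4me3"}))


class TestBrainSpecificity:
    def cage(self, expr):
        return CagePeak(GenomicInterval("chrS", 1, 100), "+", expr)

    def test_brain_dominant(self):
        r = brain_specificity(self.cage({"brain": 10.0, "liver": 1.0}), {"brain"})
        assert r == BrainSpecificity(10.0, 1.0, True)

    def test_other_dominant(self):
        assert not brain_specificity(self.cage({"brain": 0.0, "liver": 5.0}), {"brain"}).brain_specific

    def test_tie_is_not_specific(self):
        assert not brain_specificity(self.cage({"brain": 5.0, "liver": 5.0}), {"brain"}).brain_specific

    def test_missing_brain_tissues_indeterminate(self):
        r = brain_specificity(self.cage({"liver": 5.0}), {"brain"})
        assert r.indeterminate and not r.brain_specific

    def test_empty_expression_rejected(self):
        with pytest.raises(ValueError):
            brain_specificity(self.cage({}), {"brain"})


def build_candidate(**kw):
    base = dict(
        region=StrandedInterval(REGION, "+"),
        sros=[SRO(GenomicInterval("chrS", 900, 1500), frozenset({"c1", "c2", "c3"}))],
        tfbs=[GenomicInterval("chrS", 1200, 1220)],
        cage=[CagePeak(GenomicInterval("chrS", 1050, 1150), "+", {"fetal_brain": 20.0})],
        me3_me1=3.0,
        delta_sites=[CoverageStep(1500, 46)],
    )
    base.update(kw)
    return evaluate_candidate(**base)


class TestEvaluateCandidate:
    def test_all_criteria_met_passes(self):
        cand = build_candidate()
        assert cand.passes_filter
        assert cand.deleted_in_cases == 3

    def test_missing_cage_fails(self):
        assert not build_candidate(cage=[]).passes_filter

    def test_missing_tfbs_fails(self):
        assert not build_candidate(tfbs=[]).passes_filter

    def test_ratio_not_strictly_above_one_fails(self):
        assert not build_candidate(me3_me1=1.0).passes_filter

    def test_no_delta_site_fails(self):
        assert not build_candidate(delta_sites=[]).passes_filter

    def test_no_case_deletion_fails(self):
        assert not build_candidate(sros=[]).passes_filter

    def test_filter_is_monotone_in_evidence(self):
        # adding evidence to a passing candidate can never revoke the pass
        cand = build_candidate()
        richer = build_candidate(
            tfbs=[GenomicInterval("chrS", 1200, 1220), GenomicInterval("chrS", 1400, 1410)],
            cage=[
                CagePeak(GenomicInterval("chrS", 1050, 1150), "+", {"fetal_brain": 20.0}),
                CagePeak(GenomicInterval("chrS", 1300, 1320), "+", {"adult_brain": 5.0}),
            ],
            delta_sites=[CoverageStep(1500, 46), CoverageStep(1600, 25)],
            sros=[
                SRO(GenomicInterval("chrS", 900, 1500), frozenset({"c1", "c2", "c3"})),
                SRO(GenomicInterval("chrS", 1501, 1800), frozenset({"c4"})),
            ],
        )
        assert cand.passes_filter and richer.passes_filter
        assert richer.deleted_in_cases >= cand.deleted_in_cases

    def test_control_counts_from_shared_partition(self):
        sros = [
            SRO(
                GenomicInterval("chrS", 900, 1500),
                frozenset({"c1"}),
                {"ctrl": frozenset({"k1", "k2"})},
            )
        ]
        cand = build_candidate(sros=sros)
        assert cand.deleted_in_controls == {"ctrl": 2}


class TestSyntheticLocusFilter:
    """Construct-and-check on the seeded synthetic locus."""

    def test_planted_elements_pass(self, locus):
        from cfescan.promoter import me3_me1_ratio
        from cfescan.splicing import scan_coverage_steps
        from cfescan.sro import build_sros

        deletions = [r for recs in locus.cohorts.values() for r in recs]
        sros = build_sros(deletions)
        for el in locus.config.planted_elements:
            cand = evaluate_candidate(
                StrandedInterval(el.promoter, "+"),
                sros,
                locus.tfbs,
                locus.cage,
                me3_me1_ratio(el.promoter, locus.peaks, tissue="fetal_brain"),
                scan_coverage_steps(locus.coverage, el.promoter, 20, "+"),
            )
            assert cand.passes_filter, el.name

    def test_decoys_never_pass(self, locus):
        from cfescan.promoter import me3_me1_ratio
        from cfescan.splicing import scan_coverage_steps
        from cfescan.sro import build_sros

        deletions = [r for recs in locus.cohorts.values() for r in recs]
        sros = build_sros(deletions)
        for decoy in locus.config.decoys:
            tfbs = [] if decoy.missing == "tfbs" else locus.tfbs
            cand = evaluate_candidate(
                StrandedInterval(decoy.region, "+"),
                sros,
                locus.tfbs,
                locus.cage,
                me3_me1_ratio(decoy.region, locus.peaks, tissue="fetal_brain"),
                scan_coverage_steps(locus.coverage, decoy.region, 20, "+"),
            )
            assert not cand.passes_filter, decoy.name


def test_candidate_region_invariant_is_exact_conjunction():
    cand = CandidateRegion(
        region=StrandedInterval(REGION, "-"),
        deleted_in_cases=1,
        tfbs_present=True,
        cage_present=True,
        me3_me1_ratio=math.inf,
        delta_sites=(CoverageStep(1500, 20),),
    )
    assert cand.passes_filter
    assert not dataclasses.replace(cand, cage_present=False).passes_filter
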