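"""Coverage-step scanning, donor consensus and first-exon calling."""

import numpy as np
import pytest

from cfescan.intervals import GenomicInterval, SequenceRecord, reverse_complement
from cfescan.splicing import (
    CoverageStep,
    CoverageTrack,
    JunctionRecord,
    call_first_exon,
    donor_consensus_check,
    last_exonic_pos,
    recursive_motif_absent,
    scan_coverage_steps,
)


def track_from(depths, origin=1):
    return CoverageTrack("chrS", origin, np.array(depths, dtype=np.int64))


class TestScanCoverageSteps:
    def test_planted_step_60_to_14(self):
        t = track_from([60] * 50 + [14] * 50, origin=101)
        (step,) = scan_coverage_steps(t, GenomicInterval("chrS", 110, 190), min_delta=20)
        assert (step.pos, step.delta) == (150, 46)

    def test_constant_track_has_no_steps(self):
        t = track_from([30] * 100)
        assert scan_coverage_steps(t, GenomicInterval("chrS", 10, 90), min_delta=20) == []

    def test_threshold_is_inclusive_at_min_delta(self):
        t = track_from([40] * 10 + [21] * 10 + [1] * 10)
        region = GenomicInterval("chrS", 1, 29)
        assert scan_coverage_steps(t, region, min_delta=20) == [CoverageStep(20, 20)]
        # the 19-drop at pos 10 is below a threshold of 20
        assert [s.pos for s in scan_coverage_steps(t, region, min_delta=19)] == [10, 20]

    def test_region_outside_track_is_an_error(self):
        t = track_from([1] * 10)
        with pytest.raises(ValueError):
            scan_coverage_steps(t, GenomicInterval("chrS", 5, 20), min_delta=1)

    def test_minus_strand_detects_forward_upward_steps(self):
        # minus-strand gene: exon occupies the high-coverage right side
        t = track_from([4] * 50 + [63] * 50, origin=1)
        (step,) = scan_coverage_steps(t, GenomicInterval("chrS", 10, 90), min_delta=20, strand="-")
        assert (step.pos, step.delta) == (50, 59)
        assert last_exonic_pos(step, "-") == 51

    def test_matches_bruteforce_adjacent_difference(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            depths = rng.integers(0, 100, size=500)
            t = track_from(depths)
            region = GenomicInterval("chrS", 50, 450)
            for strand in "+-":
                got = {(s.pos, s.delta) for s in scan_coverage_steps(t, region, 25, strand)}
                expected = set()
                for p in range(1, 500):  # pair (p, p+1), 1-based
                    d = int(depths[p - 1]) - int(depths[p])
                    if strand == "-":
                        d = -d
                    last_exonic = p if strand == "+" else p + 1
                    if d >= 25 and 50 <= last_exonic <= 450:
                        expected.add((p, d))
                assert got == expected

    def test_lowering_threshold_never_removes_steps(self):
        rng = np.random.default_rng(7)
        depths = rng.integers(0, 80, size=300)
        t = track_from(depths)
        region = GenomicInterval("chrS", 10, 290)
        prev: set = set()
        for min_delta in (60, 40, 20, 10, 1):
            cur = {(s.pos, s.delta) for s in scan_coverage_steps(t, region, min_delta)}
            assert prev <= cur
            prev = cur


class TestDonorConsensus:
    def test_aggt_context_passes(self):
        genome = SequenceRecord("g", "TTTAGGTCCC")
        site = donor_consensus_check(genome, CoverageStep(5, 46), "+")
        assert site.context == "AGGT" and site.passes

    def test_non_consensus_fails(self):
        genome = SequenceRecord("g", "TTTAGGCCCC")
        assert not donor_consensus_check(genome, CoverageStep(5, 46), "+").passes

    def test_minus_strand_reverse_complements_the_window(self):
        # forward AC|CT at the mirrored boundary reads AG|GT on the minus strand
        genome = SequenceRecord("g", "GGGACCTGGG")
        site = donor_consensus_check(genome, CoverageStep(5, 46), "-")
        assert site.context == "AGGT" and site.passes

    def test_strand_mirror_property(self):
        rng = np.random.default_rng(13)
        bases = np.array(list("ACGT"))
        for _ in range(50):
            seq = "".join(bases[rng.integers(0, 4, size=30)])
            genome = SequenceRecord("g", seq)
            mirror = SequenceRecord("g_rc", reverse_complement(seq))
            pos = int(rng.integers(2, 28))
            fwd = donor_consensus_check(genome, CoverageStep(pos, 30), "+")
            # the pair (pos, pos+1) maps to (L-pos, L-pos+1) on the reverse complement
            rev = donor_consensus_check(mirror, CoverageStep(len(seq) - pos, 30), "-")
            assert fwd.context == rev.context and fwd.passes == rev.passes

    def test_boundary_at_sequence_edge_errors(self):
        genome = SequenceRecord("g", "ACGTACGT")
        with pytest.raises(ValueError):
            donor_consensus_check(genome, CoverageStep(1, 5), "+")
        with pytest.raises(ValueError):
            donor_consensus_check(genome, CoverageStep(7, 5), "+")


class TestCoverageStepNotation:
    @pytest.mark.parametrize(
        "pos,expected", [(84431338, "84431338-9"), (84148430, "84148430-1"), (99, "99-100")]
    )
    def test_two_base_printed_form(self, pos, expected):
        assert CoverageStep(pos, 46).notation() == expected


class TestCallFirstExon:
    def test_recovers_planted_boundaries_on_synthetic_locus(self, locus):
        for el in locus.config.planted_elements:
            steps = scan_coverage_steps(locus.coverage, el.promoter, 20, "+")
            call = call_first_exon(
                el.promoter, steps, locus.junctions, locus.gene.exons, locus.genome, "+"
            )
            assert call is not None, el.name
            assert call.coding_end == el.boundary_pos
            assert call.donor.context == "AGGT"
            assert call.acceptor_exon.start == locus.truth.acceptor_starts[el.name]

    def test_incoming_junction_acceptor_vetoes_call(self, locus):
        el = locus.config.planted_elements[0]
        steps = scan_coverage_steps(locus.coverage, el.promoter, 20, "+")
        poison = list(locus.junctions) + [
            JunctionRecord("chrS", 5_000, el.promoter.start + 10, 9, "+")
        ]
        assert call_first_exon(el.promoter, steps, poison, locus.gene.exons, locus.genome, "+") is None

    def test_no_outgoing_junction_means_no_call(self, locus):
        el = locus.config.planted_elements[0]
        steps = scan_coverage_steps(locus.coverage, el.promoter, 20, "+")
        assert call_first_exon(el.promoter, steps, [], locus.gene.exons, locus.genome, "+") is None

    def test_no_consensus_step_means_no_call(self):
        genome = SequenceRecord("chrS", "A" * 100)  # no AG|GT anywhere
        region = GenomicInterval("chrS", 10, 60)
        steps = [CoverageStep(30, 46)]
        junctions = [JunctionRecord("chrS", 30, 80, 10, "+")]
        exons = [GenomicInterval("chrS", 75, 90)]
        assert call_first_exon(region, steps, junctions, exons, genome, "+") is None

    def test_largest_delta_wins_ties_to_downstream(self):
        seq = list("C" * 100)
        for p in (30, 50):  # two consensus boundaries
            seq[p - 2 : p + 2] = list("AGGT")
        genome = SequenceRecord("chrS", "".join(seq))
        region = GenomicInterval("chrS", 10, 60)
        steps = [CoverageStep(30, 46), CoverageStep(50, 46)]  # tie -> downstream (50)
        junctions = [
            JunctionRecord("chrS", 30, 80, 10, "+"),
            JunctionRecord("chrS", 50, 80, 10, "+"),
        ]
        exons = [GenomicInterval("chrS", 75, 90)]
        call = call_first_exon(region, steps, junctions, exons, genome, "+")
        assert call is not None and call.coding_end == 50


class TestRecursiveMotif:
    def test_synthetic_cfes_built_motif_free(self, locus):
        for el in locus.config.planted_elements:
            assert recursive_motif_absent(locus.genome, el.cfe_region)

    def test_inserted_motif_detected(self):
        genome = SequenceRecord("g", "GGGG" + "CTTAGGTGAG" + "GGGG")
        assert not recursive_motif_absent(genome, GenomicInterval("g", 1, 18))

    def test_short_region_vacuously_true(self):
        genome = SequenceRecord("g", "CTTAGGTGAG")
        assert recursive_motif_absent(genome, GenomicInterval("g", 1, 5))
        assert recursive_motif_absent(genome, None)
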