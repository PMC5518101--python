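"""Exact Fisher enrichment, Bonferroni and the dual-setting rule."""

from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import hypergeom

from cfescan.cohort import CnvRecord
from cfescan.enrichment import (
    ContingencyTable,
    bonferroni,
    dual_setting_significance,
    fisher_one_tailed,
    fisher_one_tailed_exact,
    region_table,
)
from cfescan.intervals import GenomicInterval


class TestFisherOneTailed:
    def test_published_gddid_table(self):
        t = ContingencyTable(a=11, b=3, c=3, d=16)
        assert fisher_one_tailed_exact(t) == Fraction(368544, 818809200)
        assert f"{fisher_one_tailed(t):.4g}" == "0.0004501"

    def test_zero_case_hits_gives_one(self):
        assert fisher_one_tailed(ContingencyTable(a=0, b=5, c=3, d=7)) == 1.0

    def test_all_tables_with_margins_up_to_8_match_enumeration(self):
        for n1 in range(1, 9):
            for n2 in range(1, 9):
                for a in range(0, n1 + 1):
                    for c in range(0, n2 + 1):
                        t = ContingencyTable(a=a, b=n1 - a, c=c, d=n2 - c)
                        mine = fisher_one_tailed(t)
                        oracle = float(hypergeom.sf(a - 1, n1 + n2, a + c, n1))
                        assert mine == pytest.approx(oracle, rel=1e-12, abs=1e-300)

    def test_monotone_in_a_with_fixed_margins(self):
        n1, n2, k = 14, 19, 14  # k = total hits
        ps = []
        for a in range(max(0, k - n2), min(n1, k) + 1):
            t = ContingencyTable(a=a, b=n1 - a, c=k - a, d=n2 - (k - a))
            ps.append(fisher_one_tailed(t))
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(a=-1, b=3, c=3, d=16)
        with pytest.raises(ValueError):
            ContingencyTable(a=0, b=0, c=3, d=16)
        with pytest.raises(ValueError):
            ContingencyTable(a=1, b=3, c=0, d=0)


class TestBonferroni:
    def test_single_test_is_identity(self):
        (r,) = bonferroni([0.001])
        assert r.p_adjusted == 0.001 and r.significant

    def test_adjustment_and_flags(self):
        res = bonferroni([0.02, 0.04], alpha=0.05)
        assert [r.p_adjusted for r in res] == [0.04, 0.08]
        assert [r.significant for r in res] == [True, False]

    def test_capped_at_one(self):
        assert bonferroni([0.9] * 5)[0].p_adjusted == 1.0

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        ps = rng.uniform(1e-6, 1, size=20).tolist()
        for raw, r in zip(ps, bonferroni(ps)):
            assert r.p_adjusted >= raw

    def test_empty_input(self):
        assert bonferroni([]) == []


class TestDualSetting:
    tables = {
        "case-vs-dgv": ContingencyTable(a=11, b=3, c=0, d=24),
        "case-vs-gddid": ContingencyTable(a=11, b=3, c=3, d=16),
    }

    def test_significant_in_both_settings(self):
        res = dual_setting_significance("r1", self.tables, alpha=0.05)
        assert res.significant_overall
        assert set(res.settings) == set(self.tables)

    def test_one_failing_setting_blocks_overall(self):
        tables = dict(self.tables)
        tables["case-vs-gddid"] = ContingencyTable(a=4, b=10, c=3, d=16)
        assert not dual_setting_significance("r1", tables).significant_overall

    def test_order_invariance(self):
        fwd = dual_setting_significance("r", dict(self.tables))
        rev = dual_setting_significance("r", dict(reversed(list(self.tables.items()))))
        assert fwd == rev

    def test_missing_setting_named_in_error(self):
        with pytest.raises(ValueError, match="case-vs-dgv"):
            dual_setting_significance(
                "r",
                {"case-vs-gddid": self.tables["case-vs-gddid"]},
                required_settings=["case-vs-dgv", "case-vs-gddid"],
            )

    def test_fewer_than_two_settings_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            dual_setting_significance("r", {"only": self.tables["case-vs-dgv"]})

    def test_per_setting_bonferroni_multiplier(self):
        res = dual_setting_significance("r", self.tables, n_tests_by_setting=11)
        for r in res.settings.values():
            assert r.p_bonferroni == pytest.approx(min(1.0, 11 * r.p_raw))


def deletion(pid, start, end, cohort):
    return CnvRecord(pid, GenomicInterval("chrS", start, end), state="deletion", cohort=cohort)


class TestRegionTable:
    region = GenomicInterval("chrS", 1000, 2000)
    universe = GenomicInterval("chrS", 1, 10_000)

    def test_counts_patients_not_cnvs(self):
        cases = [
            deletion("a", 900, 1100, "case"),
            deletion("a", 1500, 1600, "case"),  # same patient, second CNV
            deletion("b", 3000, 4000, "case"),
        ]
        controls = [deletion("x", 5000, 6000, "ctrl")]
        t = region_table(cases, controls, self.region, self.universe)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 0, 1)

    def test_universe_equal_to_region_empties_b_and_d(self):
        cases = [deletion("a", 1000, 1500, "case")]
        controls = [deletion("x", 1200, 1300, "ctrl")]
        t = region_table(cases, controls, self.region, self.region)
        assert (t.b, t.d) == (0, 0)

    def test_empty_control_cohort_violates_invariant(self):
        cases = [deletion("a", 1000, 1500, "case")]
        with pytest.raises(ValueError):
            region_table(cases, [], self.region, self.universe)

    def test_matches_generator_truth_tables(self, locus):
        """The 2x2 tables rebuilt from the simulated cohorts equal the truth."""
        cases = locus.cohorts["case"]
        targets = [el.promoter for el in locus.config.planted_elements]
        for name in ("control-a", "control-b"):
            t = region_table(
                cases, locus.cohorts[name], targets, GenomicInterval("chrS", 1, 100_000)
            )
            expected = locus.truth.expected_tables[f"case-vs-{name}"]
            assert vars(t) == expected
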