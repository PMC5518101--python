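"""Exact one-tailed deletion enrichment testing with the dual-setting rule.

The test asks whether deletions affecting a region are over-represented in
cases: with ``a`` cases hit out of ``a+b`` and ``c`` controls hit out of
``c+d``, the one-tailed Fisher p value is the upper-tail hypergeometric
probability P(X >= a) with population ``a+b+c+d``, ``a+c`` successes and
``a+b`` draws. It is computed as an exact rational (integer binomials) and
only converted to float at the end. Bonferroni correction multiplies by the
number of regions tested in a setting; a region counts as enriched only when
the adjusted p is below alpha in every control setting.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Mapping, Sequence

from .cohort import CnvRecord, patients_overlapping
from .intervals import GenomicInterval

__all__ = [
    "ContingencyTable",
    "SettingResult",
    "EnrichmentResult",
    "fisher_one_tailed",
    "fisher_one_tailed_exact",
    "bonferroni",
    "dual_setting_significance",
    "region_table",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: cases with / without a region-affecting deletion, same for controls."""

    a: int  # cases with
    b: int  # cases without
    c: int  # controls with
    d: int  # controls without

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b < 1:
            raise ValueError("empty case margin (a + b = 0)")
        if self.c + self.d < 1:
            raise ValueError("empty control margin (c + d = 0)")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_one_tailed_exact(t: ContingencyTable) -> Fraction:
    """Upper-tail hypergeometric probability P(X >= a), as an exact rational."""
    n_pop = t.total
    n_success = t.a + t.c
    n_draw = t.a + t.b
    hi = min(n_success, n_draw)
    num = sum(comb(n_success, x) * comb(n_pop - n_success, n_draw - x) for x in range(t.a, hi + 1))
    return Fraction(num, comb(n_pop, n_draw))


def fisher_one_tailed(t: ContingencyTable) -> float:
    """One-tailed Fisher's exact test for deletion enrichment in cases.

    Exact rational computation; the only rounding is the final conversion
    to float.
    """
    return float(fisher_one_tailed_exact(t))


@dataclass(frozen=True)
class BonferroniItem:
    p_raw: float
    p_adjusted: float
    n_tests: int
    significant: bool


def bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> list[BonferroniItem]:
    """Bonferroni adjustment: p_adj = min(1, m * p) with m = len(p_values)."""
    m = len(p_values)
    out = []
    for p in p_values:
        if not (0 < p <= 1):
            raise ValueError(f"p value must lie in (0, 1], got {p}")
        p_adj = min(1.0, m * p)
        out.append(BonferroniItem(p_raw=p, p_adjusted=p_adj, n_tests=m, significant=p_adj < alpha))
    return out


@dataclass(frozen=True)
class SettingResult:
    """Enrichment outcome for one case-vs-control setting."""

    table: ContingencyTable
    p_raw: float
    p_bonferroni: float
    n_tests: int
    significant: bool

    def __post_init__(self) -> None:
        expected = min(1.0, self.n_tests * self.p_raw)
        if abs(self.p_bonferroni - expected) > 1e-12:
            raise ValueError("p_bonferroni inconsistent with n_tests * p_raw")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-region enrichment across all settings; overall flag is the conjunction."""

    region_id: str
    settings: Mapping[str, SettingResult]
    alpha: float
    significant_overall: bool


def dual_setting_significance(
    region_id: str,
    tables_by_setting: Mapping[str, ContingencyTable],
    alpha: float = 0.05,
    n_tests_by_setting: Mapping[str, int] | int = 1,
    required_settings: Sequence[str] | None = None,
) -> EnrichmentResult:
    """Apply the dual-setting rule: enriched iff adjusted p < alpha in EVERY setting.

    Each setting (one control cohort) carries its own Bonferroni multiplier
    ``m`` (the number of regions scanned in that setting; 1 for a
    single-region reproduction, where the raw p is reported). At least two
    settings are required; a missing required setting raises an error naming
    it.
    """
    if required_settings is not None:
        missing = [s for s in required_settings if s not in tables_by_setting]
        if missing:
            raise ValueError(f"missing setting(s): {', '.join(missing)}")
    if len(tables_by_setting) < 2:
        raise ValueError(
            f"dual-setting significance needs >= 2 settings, got {len(tables_by_setting)}"
        )
    results: dict[str, SettingResult] = {}
    for name in sorted(tables_by_setting):
        table = tables_by_setting[name]
        m = n_tests_by_setting if isinstance(n_tests_by_setting, int) else n_tests_by_setting[name]
        if m < 1:
            raise ValueError(f"setting {name!r}: n_tests must be >= 1")
        p = fisher_one_tailed(table)
        p_adj = min(1.0, m * p)
        results[name] = SettingResult(
            table=table, p_raw=p, p_bonferroni=p_adj, n_tests=m, significant=p_adj < alpha
        )
    return EnrichmentResult(
        region_id=region_id,
        settings=results,
        alpha=alpha,
        significant_overall=all(r.significant for r in results.values()),
    )


def region_table(
    cases: Sequence[CnvRecord],
    controls: Sequence[CnvRecord],
    region: GenomicInterval | Sequence[GenomicInterval],
    universe: GenomicInterval,
) -> ContingencyTable:
    """Build the 2x2 table for one region against an explicit analysis universe.

    The counting unit is the patient. ``a`` = distinct case patients with a
    deletion overlapping the region (any of several regions); ``b`` = case
    patients with a deletion in the universe but none overlapping the
    region; ``c``/``d`` likewise for controls. The universe (e.g. all
    deletions overlapping a locus of interest) must be supplied explicitly —
    there is no implicit genome-wide denominator.
    """

    def split(cohort: Sequence[CnvRecord]) -> tuple[int, int]:
        in_universe = patients_overlapping(cohort, universe)
        hit = patients_overlapping(cohort, region) & in_universe
        return len(hit), len(in_universe - hit)

    a, b = split(cases)
    c, d = split(controls)
    return ContingencyTable(a=a, b=b, c=c, d=d)
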