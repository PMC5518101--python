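"""End-to-end workflows.

``run_scan`` wires the stages of the knowledge-driven discovery scan:
cohort filtering -> deletion SROs -> H3K4me3 candidate regions -> the
four-criterion promoter filter -> first-exon calling -> per-setting exact
enrichment with Bonferroni correction and the dual-setting rule.

``run_dlg2_reproduction`` replays the packaged DLG2 fixture: it recomputes
the HPin7/HPin8 overlap counts, the any-HP percentage, the GDD/ID Fisher p
value and the candidate-row width from the raw fixture data and compares
each against the printed reference value. Verdicts are computed, never
stored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import io as cio
from .cohort import CnvRecord, DELETION, filter_cnvs, count_overlapping
from .enrichment import (
    ContingencyTable,
    EnrichmentResult,
    dual_setting_significance,
    fisher_one_tailed,
    region_table,
)
from .fixtures import dlg2_fixture
from .intervals import GenomicInterval, StrandedInterval, intervals_overlap
from .promoter import CandidateRegion, evaluate_candidate, me3_me1_ratio
from .splicing import CfeCall, call_first_exon, scan_coverage_steps
from .sro import SRO, build_sros

__all__ = ["PipelineConfig", "ScanResult", "run_scan", "run_dlg2_reproduction", "format_percent"]

log = logging.getLogger("cfescan")


@dataclass
class PipelineConfig:
    """File paths and thresholds for one scan run.

    ``universe`` (the denominator of every 2x2 table, e.g. "all deletions
    overlapping the locus of interest") must be stated explicitly; there is
    no implicit genome-wide default.
    """

    cohort_paths: list[str]
    peak_paths: list[str]
    cage_path: str
    tfbs_path: str
    coverage_path: str
    junctions_path: str
    gene_model_path: str
    genome_path: str
    universe: GenomicInterval
    case_cohorts: frozenset[str] = frozenset({"case"})
    control_cohorts: tuple[str, ...] = ()  # empty -> every non-case cohort seen
    tissue: str | None = None
    min_delta: int = 20
    min_case: int = 1
    alpha: float = 0.05
    ratio_statistic: str = "max_signal"
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        u = raw.pop("universe")
        raw["universe"] = GenomicInterval(u["chrom"], u["start"], u["end"])
        if "case_cohorts" in raw:
            raw["case_cohorts"] = frozenset(raw["case_cohorts"])
        if "control_cohorts" in raw:
            raw["control_cohorts"] = tuple(raw["control_cohorts"])
        return cls(**raw)


@dataclass
class ScanResult:
    candidates: list[CandidateRegion]
    cfe_calls: dict[str, CfeCall | None]  # candidate region str -> call
    enrichment: list[EnrichmentResult]
    sros: list[SRO] = field(default_factory=list)

    def passing(self) -> list[CandidateRegion]:
        return [c for c in self.candidates if c.passes_filter]

    def significant(self) -> list[EnrichmentResult]:
        return [e for e in self.enrichment if e.significant_overall]


def _merge_intervals(ivs: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    for iv in sorted(ivs):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end + 1:
            out[-1] = GenomicInterval(iv.chrom, out[-1].start, max(out[-1].end, iv.end))
        else:
            out.append(iv)
    return out


def _host_intron(region: GenomicInterval, gene: cio.GeneModel) -> str | None:
    for i, intron in enumerate(gene.introns(), start=1):
        if intron.contains(region):
            return f"intron {i}"
    return None


def run_scan(config: PipelineConfig) -> ScanResult:
    """Execute the knowledge-driven scan and (optionally) write its reports."""
    records: list[CnvRecord] = []
    for p in config.cohort_paths:
        records.extend(cio.read_cohort_tsv(p))
    n_raw = len(records)
    records = filter_cnvs(records)
    deletions = [r for r in records if r.state == DELETION]
    log.info("cohorts: %d records read, %d retained by filter, %d deletions", n_raw, len(records), len(deletions))

    cohort_names = sorted({r.cohort for r in deletions})
    case_names = {c for c in cohort_names if c in config.case_cohorts}
    control_names = list(config.control_cohorts) or [c for c in cohort_names if c not in config.case_cohorts]
    case_records = [r for r in deletions if r.cohort in case_names]
    controls_by_name = {name: [r for r in deletions if r.cohort == name] for name in control_names}
    if not case_records:
        log.warning("no case deletions after filtering; candidate table will be empty")

    peaks = []
    for p in config.peak_paths:
        peaks.extend(cio.read_narrowpeak(p))
    cage = cio.read_cage_bed(config.cage_path)
    tfbs = [r.interval for r in cio.read_bed(config.tfbs_path)]
    junctions = cio.read_junctions_tsv(config.junctions_path)
    genes = cio.read_gene_model_bed12(config.gene_model_path)
    genomes = cio.read_fasta(config.genome_path)

    # deletion SROs per chromosome, all cohorts counted on the shared partition
    sros: list[SRO] = []
    for chrom in sorted({d.interval.chrom for d in deletions}):
        sros.extend(
            build_sros([d for d in deletions if d.interval.chrom == chrom], case_cohorts=case_names)
        )
    log.info("SRO partition: %d segments", len(sros))

    # candidate regions: merged H3K4me3 peak footprints (designated tissue)
    me3 = [
        p.interval
        for p in peaks
        if p.marker == "H3K4me3" and (config.tissue is None or p.tissue == config.tissue)
    ]
    regions = _merge_intervals(me3)
    case_sros = [s for s in sros if s.case_count >= config.min_case]
    regions = [
        r for r in regions if any(intervals_overlap(r, s.interval) for s in case_sros)
    ]
    log.info("candidate H3K4me3 regions overlapping case SROs: %d", len(regions))

    candidates: list[CandidateRegion] = []
    cfe_calls: dict[str, CfeCall | None] = {}
    tracks: dict[str, object] = {}
    for region in regions:
        gene = next((g for g in genes if g.chrom == region.chrom and _host_intron(region, g)), None)
        strand = gene.strand if gene else "+"
        genome = genomes.get(region.chrom)
        steps = []
        if genome is not None:
            if region.chrom not in tracks:
                tracks[region.chrom] = cio.read_bedgraph(config.coverage_path, chrom=region.chrom)
            steps = scan_coverage_steps(
                tracks[region.chrom], region, min_delta=config.min_delta, strand=strand
            )
        ratio = me3_me1_ratio(region, peaks, tissue=config.tissue, statistic=config.ratio_statistic)
        call = None
        if genome is not None and gene is not None:
            call = call_first_exon(region, steps, junctions, gene.exons, genome, strand=strand)
        cand = evaluate_candidate(
            StrandedInterval(region, strand),
            sros,
            tfbs,
            cage,
            ratio,
            steps,
            splice_site=call.donor if call else None,
            host_gene=gene.name if gene else "",
            host_intron=_host_intron(region, gene) or "" if gene else "",
        )
        candidates.append(cand)
        cfe_calls[str(region)] = call

    passing = [c for c in candidates if c.passes_filter]
    m = max(1, len(passing))
    enrichment: list[EnrichmentResult] = []
    for cand in passing:
        tables: dict[str, ContingencyTable] = {}
        for name in control_names:
            tables[f"case-vs-{name}"] = region_table(
                case_records, controls_by_name[name], cand.region.interval, config.universe
            )
        if len(tables) >= 2:
            enrichment.append(
                dual_setting_significance(
                    str(cand.region.interval), tables, alpha=config.alpha, n_tests_by_setting=m
                )
            )
        else:
            log.warning("fewer than two control settings; skipping dual-setting test")
    log.info(
        "filter: %d/%d candidates pass; %d significant in all settings",
        len(passing),
        len(candidates),
        sum(e.significant_overall for e in enrichment),
    )

    result = ScanResult(candidates=candidates, cfe_calls=cfe_calls, enrichment=enrichment, sros=sros)
    if config.outdir:
        _write_scan_outputs(result, Path(config.outdir))
    return result


def _candidate_rows(result: ScanResult) -> pd.DataFrame:
    rows = []
    by_region = {e.region_id: e for e in result.enrichment}
    for i, c in enumerate(sorted(result.candidates, key=lambda c: (c.region.interval))):
        iv = c.region.interval
        call = result.cfe_calls.get(str(iv))
        enr = by_region.get(str(iv))
        rows.append(
            {
                "entry": chr(ord("a") + i) if i < 26 else str(i),
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "width": iv.width,
                "gene": c.host_gene,
                "strand": c.region.strand,
                "n_cases": c.deleted_in_cases,
                "n_controls": sum(c.deleted_in_controls.values()),
                "splicing_site": call.donor.boundary.notation() if call else "",
                "type": c.annotation_type,
                "me3_me1_ratio": "inf" if c.me3_me1_ratio == float("inf") else round(c.me3_me1_ratio, 3),
                "tfbs": c.tfbs_present,
                "cage": c.cage_present,
                "n_delta_sites": len(c.delta_sites),
                "passes_filter": c.passes_filter,
                "enriched": enr.significant_overall if enr else False,
            }
        )
    return pd.DataFrame(rows)


def _enrichment_rows(result: ScanResult) -> pd.DataFrame:
    rows = []
    for e in result.enrichment:
        for setting, r in e.settings.items():
            rows.append(
                {
                    "region": e.region_id,
                    "setting": setting,
                    "a": r.table.a,
                    "b": r.table.b,
                    "c": r.table.c,
                    "d": r.table.d,
                    "p_raw": r.p_raw,
                    "p_bonferroni": r.p_bonferroni,
                    "n_tests": r.n_tests,
                    "significant": r.significant,
                    "significant_overall": e.significant_overall,
                }
            )
    return pd.DataFrame(rows)


def _write_scan_outputs(result: ScanResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _candidate_rows(result).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    _enrichment_rows(result).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    report = {
        "n_candidates": len(result.candidates),
        "n_passing": len(result.passing()),
        "significant_regions": sorted(e.region_id for e in result.significant()),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))


def format_percent(numerator: int, denominator: int) -> int:
    """Integer-rounded percentage (26/29 -> 90)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100 * numerator / denominator)


def _sig4(x: float) -> float:
    """Round to 4 significant digits (printed-p comparison aid)."""
    return float(f"{x:.4g}")


def run_dlg2_reproduction() -> dict:
    """Recompute the DLG2 fixture quantities and compare with the printed values.

    Every "computed" entry is derived at call time from the raw fixture
    coordinates/counts; the "printed" entries come from the published
    tables. Mutating a fixture coordinate flips the corresponding verdict.
    """
    fx = dlg2_fixture()
    patients = list(fx.patients)
    ref = fx.reference_values

    hp7 = count_overlapping(patients, fx.hpin7)
    hp8 = count_overlapping(patients, fx.hpin8)
    either = count_overlapping(patients, [fx.hpin7, fx.hpin8], mode="any")
    both = count_overlapping(patients, [fx.hpin7, fx.hpin8], mode="all")
    pct = format_percent(either, len(patients))
    p = fisher_one_tailed(fx.gddid_table())
    entry = fx.candidate_rows["HPin8_entry"]
    width = GenomicInterval(entry["chrom"], entry["start"], entry["end"]).width

    checks = [
        ("deletions affecting HPin7", hp7, ref["hpin7_deletions"]),
        ("deletions affecting HPin8", hp8, ref["hpin8_deletions"]),
        ("deletions affecting either HP", either, ref["either_hp_deletions"]),
        ("deletions affecting both HPs", both, ref["both_hp_deletions"]),
        ("inclusion-exclusion (7 + 8 - both)", hp7 + hp8 - both, ref["either_hp_deletions"]),
        ("percent of patients missing an HP", pct, ref["either_hp_percent"]),
        ("GDD/ID any-HP Fisher p (4 s.d.)", _sig4(p), ref["gddid_any_hp_p"]),
        ("HPin8 candidate-row width", width, ref["hpin8_entry_width"]),
    ]
    return {
        "n_patients": len(patients),
        "gddid_table": vars(fx.gddid_table()),
        "p_raw": p,
        "checks": [
            {"name": name, "computed": computed, "printed": printed, "pass": computed == printed}
            for name, computed, printed in checks
        ],
        "all_pass": all(computed == printed for _, computed, printed in checks),
    }
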