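"""Seeded synthetic locus generator.

Builds a fully self-contained toy chromosome that exhibits the statistical
structure the discovery pipeline assumes: a multi-exon gene with long
introns; planted intronic promoter elements carrying promoter-like
chromatin (H3K4me3 above H3K4me1), TFBS and brain-leaning CAGE peaks; an
expressed first exon inside each element whose 3' boundary is an abrupt
per-base coverage drop with an AG|GT genomic context and a split-read
junction into a downstream annotated exon; decoy regions each missing
exactly one filter criterion; and case/control deletion cohorts with a
configurable per-patient probability of hitting a planted element.

Default parameters mirror the study conditions of the locus the pipeline
reproduces: cohort sizes 14 cases versus two control cohorts of 19, hit
probabilities 11/14 and 3/19, planted coverage deltas 46 and 59 on an
exonic depth of 60, and the CNV filter limits (50 bp - 3 Mbp,
|log2ratio| >= 0.32) respected by construction.

Determinism: every output stream draws from its own child of the master
seed, so identical seeds give byte-identical files and adding a new output
type does not perturb the existing ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .cohort import CnvRecord, DELETION
from .intervals import (
    GenomicInterval,
    SequenceRecord,
    intervals_overlap,
    iupac_scan,
)
from .io import (
    GeneModel,
    write_bedgraph,
    write_bed,
    BedRecord,
    write_cage_bed,
    write_cohort_tsv,
    write_fasta,
    write_gene_model_bed12,
    write_junctions_tsv,
    write_narrowpeak,
)
from .promoter import CagePeak, PeakRecord
from .splicing import CoverageTrack, JunctionRecord, RECURSIVE_EXON_MOTIF

__all__ = [
    "PlantedElement",
    "DecoyRegion",
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticLocus",
    "default_config",
    "build_locus",
    "simulate_cohorts",
    "generate_dataset",
    "CASE_COHORT",
    "CONTROL_COHORTS",
]

CASE_COHORT = "case"
CONTROL_COHORTS = ("control-a", "control-b")

# child-seed identifiers, one pseudo-random stream per output type
_STREAMS = {"sequence": 11, "coverage": 12, "peaks": 13, "cage": 14, "tfbs": 15, "junctions": 16, "cohorts": 17}


@dataclass(frozen=True)
class PlantedElement:
    """One planted intronic promoter + coding first exon (plus-strand gene)."""

    name: str
    promoter: GenomicInterval  # the H3K4me3 peak region
    cfe_start: int  # 5' end of the expressed first exon
    boundary_pos: int  # last exonic base (donor side of the coverage step)
    delta: int  # planted coverage drop at the boundary
    acceptor_exon: int  # index into the gene model's exons

    def __post_init__(self) -> None:
        if not (self.promoter.start <= self.cfe_start < self.boundary_pos <= self.promoter.end):
            raise ValueError(f"element {self.name}: CFE must lie inside the promoter region")
        if self.delta < 1:
            raise ValueError(f"element {self.name}: delta must be >= 1")

    @property
    def cfe_region(self) -> GenomicInterval:
        return GenomicInterval(self.promoter.chrom, self.cfe_start, self.boundary_pos)


@dataclass(frozen=True)
class DecoyRegion:
    """A region engineered to miss exactly one filter criterion."""

    name: str
    region: GenomicInterval
    missing: str  # one of: tfbs, cage, ratio, delta
    boundary_pos: int | None = None
    delta: int | None = None

    def __post_init__(self) -> None:
        if self.missing not in ("tfbs", "cage", "ratio", "delta"):
            raise ValueError(f"decoy {self.name}: unknown missing criterion {self.missing!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int
    chrom: str = "chrS"
    chrom_length: int = 100_000
    gene: GeneModel | None = None  # None -> default 4-exon plus-strand model
    planted_elements: tuple[PlantedElement, ...] = ()
    decoys: tuple[DecoyRegion, ...] = ()
    n_case: int = 14
    n_control: int = 19  # per control cohort
    p_hit_case: float = 11 / 14
    p_hit_control: float = 3 / 19
    del_min_bp: int = 5_000
    del_max_bp: int = 40_000
    background_depth: int = 60  # exonic depth of the planted first exon
    baseline_depth: int = 5  # nascent intronic transcription
    exon_depth: int = 80  # annotated-exon depth
    motif_free: bool = True  # scrub the recursive exon motif from planted CFEs
    tissue: str = "fetal_brain"

    def validate(self) -> None:
        if not (0 <= self.p_hit_control <= self.p_hit_case <= 1):
            raise ValueError("need 0 <= p_hit_control <= p_hit_case <= 1")
        if self.gene is None:
            raise ValueError("config has no gene model (use default_config)")
        if self.del_min_bp < 50 or self.del_max_bp > 3_000_000 or self.del_min_bp > self.del_max_bp:
            raise ValueError("deletion lengths must satisfy 50 <= min <= max <= 3e6")
        introns = self.gene.introns()
        for el in self.planted_elements:
            if el.delta < 1:
                raise ValueError(f"{el.name}: delta must be >= 1")
            if not any(i.contains(el.promoter) for i in introns):
                raise ValueError(f"planted element {el.name} not inside an intron")
            if not (0 <= el.acceptor_exon < len(self.gene.exons)):
                raise ValueError(f"{el.name}: acceptor exon index out of range")
        for d in self.decoys:
            if not any(i.contains(d.region) for i in introns):
                raise ValueError(f"decoy {d.name} not inside an intron")
        if self.background_depth <= self.baseline_depth:
            raise ValueError("background_depth must exceed baseline_depth")


def default_config(seed: int, **overrides) -> SyntheticConfig:
    """The default study-condition locus: two planted elements, four decoys.

    The two elements carry the reproduction deltas (46 and 59); each decoy
    drops exactly one criterion (no TFBS, no CAGE, me3/me1 ratio <= 1, no
    abrupt step >= 20).
    """
    chrom = overrides.pop("chrom", "chrS")
    gene = GeneModel(
        name="synGene",
        chrom=chrom,
        strand="+",
        exons=(
            GenomicInterval(chrom, 3_000, 3_200),
            GenomicInterval(chrom, 40_000, 40_180),
            GenomicInterval(chrom, 62_000, 62_150),
            GenomicInterval(chrom, 90_000, 90_400),
        ),
    )
    planted = (
        PlantedElement(
            name="planted-in1",
            promoter=GenomicInterval(chrom, 18_000, 19_500),
            cfe_start=18_650,
            boundary_pos=18_900,
            delta=46,
            acceptor_exon=1,
        ),
        PlantedElement(
            name="planted-in2",
            promoter=GenomicInterval(chrom, 50_000, 51_300),
            cfe_start=50_350,
            boundary_pos=50_600,
            delta=59,
            acceptor_exon=2,
        ),
    )
    decoys = (
        DecoyRegion("decoy-no-tfbs", GenomicInterval(chrom, 65_000, 66_000), "tfbs", 65_500, 46),
        DecoyRegion("decoy-no-cage", GenomicInterval(chrom, 70_000, 71_000), "cage", 70_500, 46),
        DecoyRegion("decoy-low-ratio", GenomicInterval(chrom, 75_000, 76_000), "ratio", 75_500, 46),
        DecoyRegion("decoy-no-delta", GenomicInterval(chrom, 80_000, 81_000), "delta", 80_500, 10),
    )
    cfg = SyntheticConfig(
        seed=seed, chrom=chrom, gene=gene, planted_elements=planted, decoys=decoys, **overrides
    )
    cfg.validate()
    return cfg


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth, derivable deterministically from config + seed."""

    elements: tuple[PlantedElement, ...]
    decoys: tuple[DecoyRegion, ...]
    donor_contexts: Mapping[str, str]  # element name -> 4-nt context
    acceptor_starts: Mapping[str, int]  # element name -> acceptor exon start
    patient_hits: Mapping[str, Mapping[str, bool]]  # cohort -> patient -> any-element hit
    expected_tables: Mapping[str, Mapping[str, int]]  # setting -> {a, b, c, d}

    def to_jsonable(self) -> dict:
        return {
            "elements": [
                {
                    "name": e.name,
                    "promoter": str(e.promoter),
                    "cfe_start": e.cfe_start,
                    "boundary_pos": e.boundary_pos,
                    "delta": e.delta,
                    "acceptor_exon": e.acceptor_exon,
                }
                for e in self.elements
            ],
            "decoys": [
                {"name": d.name, "region": str(d.region), "missing": d.missing}
                for d in self.decoys
            ],
            "donor_contexts": dict(self.donor_contexts),
            "acceptor_starts": dict(self.acceptor_starts),
            "patient_hits": {c: dict(h) for c, h in self.patient_hits.items()},
            "expected_tables": {s: dict(t) for s, t in self.expected_tables.items()},
        }


@dataclass
class SyntheticLocus:
    """Everything the pipeline consumes, in memory."""

    config: SyntheticConfig
    genome: SequenceRecord
    gene: GeneModel
    coverage: CoverageTrack
    peaks: list[PeakRecord]
    cage: list[CagePeak]
    tfbs: list[GenomicInterval]
    junctions: list[JunctionRecord]
    cohorts: dict[str, list[CnvRecord]]
    truth: SyntheticTruth


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stream]])


def _build_sequence(config: SyntheticConfig) -> SequenceRecord:
    rng = _rng(config, "sequence")
    bases = np.array(list("ACGT"))
    seq = rng.integers(0, 4, size=config.chrom_length)
    arr = bases[seq]

    def plant(pos: int, text: str) -> None:
        arr[pos - 1 : pos - 1 + len(text)] = list(text)

    protected: list[tuple[int, int]] = []
    boundaries = [(e.boundary_pos) for e in config.planted_elements] + [
        d.boundary_pos for d in config.decoys if d.boundary_pos is not None
    ]
    for b in boundaries:
        plant(b - 1, "AGGT")  # exonic AG | intronic GT around the step
        protected.append((b - 1, b + 2))

    if config.motif_free:
        for el in config.planted_elements:
            lo, hi = el.cfe_start, el.boundary_pos + 2
            for _ in range(100):
                window = SequenceRecord("w", "".join(arr[lo - 1 : hi]))
                hits = iupac_scan(window, RECURSIVE_EXON_MOTIF)
                if not hits:
                    break
                for h in hits:
                    # break the match at its first mutable base; A defeats the
                    # leading pyrimidine classes of the motif
                    for off in range(len(RECURSIVE_EXON_MOTIF)):
                        pos = lo + h - 1 + off
                        if not any(p0 <= pos <= p1 for p0, p1 in protected):
                            arr[pos - 1] = "A" if arr[pos - 1] != "A" else "G"
                            break
            else:  # pragma: no cover - 100 passes always suffice
                raise RuntimeError(f"could not scrub motif from {el.name}")
    return SequenceRecord(name=config.chrom, seq="".join(arr))


def _ramp_down(depth: np.ndarray, start_idx: int, from_depth: int, to_depth: int, step: int = 12) -> None:
    """Descend gradually so no adjacent difference reaches the filter threshold."""
    level = from_depth
    i = start_idx
    while level > to_depth and i < len(depth):
        level = max(to_depth, level - step)
        depth[i : i + 50] = level
        i += 50


def _build_coverage(config: SyntheticConfig) -> CoverageTrack:
    depth = np.full(config.chrom_length, config.baseline_depth, dtype=np.int64)
    for exon in config.gene.exons:
        depth[exon.start - 1 : exon.end] = config.exon_depth

    def expressed(cfe_start: int, boundary: int, high: int, drop: int) -> None:
        depth[cfe_start - 1 : boundary] = high
        post = high - drop
        tail = min(boundary + 400, config.chrom_length)
        depth[boundary : tail] = max(post, 0)
        _ramp_down(depth, tail, max(post, 0), config.baseline_depth)

    for el in config.planted_elements:
        expressed(el.cfe_start, el.boundary_pos, config.background_depth, el.delta)
    for d in config.decoys:
        if d.boundary_pos is None:
            continue
        if d.missing == "delta":
            # keep every step in the region below the filter threshold
            expressed(d.region.start + 300, d.boundary_pos, config.baseline_depth + 2 * d.delta, d.delta)
        else:
            expressed(d.region.start + 300, d.boundary_pos, config.background_depth, d.delta)
    return CoverageTrack(chrom=config.chrom, origin=1, depth=depth)


def _build_peaks(config: SyntheticConfig) -> list[PeakRecord]:
    rng = _rng(config, "peaks")
    peaks: list[PeakRecord] = []

    def add(iv: GenomicInterval, marker: str, signal: float) -> None:
        peaks.append(
            PeakRecord(
                interval=iv,
                marker=marker,
                tissue=config.tissue,
                signal=round(float(signal), 3),
                neglog10p=round(float(signal) * 1.5, 3),
            )
        )

    for el in config.planted_elements:
        add(el.promoter, "H3K4me3", rng.uniform(20, 30))
        add(el.promoter, "H3K4me1", rng.uniform(4, 9))
        add(el.promoter, "H3K27ac", rng.uniform(8, 14))
    for d in config.decoys:
        if d.missing == "ratio":
            me3 = rng.uniform(8, 12)
            add(d.region, "H3K4me3", me3)
            add(d.region, "H3K4me1", me3 + rng.uniform(2, 6))  # ratio < 1
        else:
            add(d.region, "H3K4me3", rng.uniform(20, 30))
            add(d.region, "H3K4me1", rng.uniform(4, 9))
    # a repressed stretch away from the gene, for marker-context classification
    tail = GenomicInterval(config.chrom, config.chrom_length - 4_000, config.chrom_length - 3_000)
    add(tail, "H3K27me3", rng.uniform(10, 20))
    return peaks


def _build_cage_tfbs(config: SyntheticConfig) -> tuple[list[CagePeak], list[GenomicInterval]]:
    cage_rng = _rng(config, "cage")
    tfbs_rng = _rng(config, "tfbs")
    cage: list[CagePeak] = []
    tfbs: list[GenomicInterval] = []

    def add_cage(cfe_start: int) -> None:
        iv = GenomicInterval(config.chrom, max(1, cfe_start - 80), cfe_start + 20)
        cage.append(
            CagePeak(
                interval=iv,
                strand=config.gene.strand,
                expression={
                    "fetal_brain": round(float(cage_rng.uniform(20, 40)), 2),
                    "adult_brain": round(float(cage_rng.uniform(5, 12)), 2),
                    "liver": round(float(cage_rng.uniform(0, 1.5)), 2),
                    "lung": round(float(cage_rng.uniform(0, 1.0)), 2),
                },
            )
        )

    def add_tfbs(region: GenomicInterval) -> None:
        for _ in range(2):
            s = int(tfbs_rng.integers(region.start, region.end - 30))
            tfbs.append(GenomicInterval(config.chrom, s, s + int(tfbs_rng.integers(10, 25))))

    for el in config.planted_elements:
        add_cage(el.cfe_start)
        add_tfbs(el.promoter)
    for d in config.decoys:
        if d.missing != "cage":
            add_cage(d.region.start + 300)
        if d.missing != "tfbs":
            add_tfbs(d.region)
    return cage, tfbs


def _build_junctions(config: SyntheticConfig) -> list[JunctionRecord]:
    rng = _rng(config, "junctions")
    out: list[JunctionRecord] = []
    exons = config.gene.exons
    for el in config.planted_elements:
        out.append(
            JunctionRecord(
                chrom=config.chrom,
                donor_pos=el.boundary_pos,
                acceptor_pos=exons[el.acceptor_exon].start,
                read_count=max(1, el.delta + int(rng.integers(-5, 6))),
                strand=config.gene.strand,
            )
        )
    # canonical junctions between annotated exons
    for a, b in zip(exons, exons[1:]):
        out.append(
            JunctionRecord(
                chrom=config.chrom,
                donor_pos=a.end,
                acceptor_pos=b.start,
                read_count=int(rng.integers(30, 70)),
                strand=config.gene.strand,
            )
        )
    return out


def _draw_deletion(
    rng: np.random.Generator, config: SyntheticConfig, hit: bool
) -> GenomicInterval:
    """One deletion, uniform conditional on hit / non-hit of any planted element."""
    targets = [el.promoter for el in config.planted_elements]
    length = int(rng.integers(config.del_min_bp, config.del_max_bp + 1))
    if hit:
        target = targets[int(rng.integers(0, len(targets)))]
        lo = max(1, target.start - length + 1)
        hi = min(target.end, config.chrom_length - length + 1)
        start = int(rng.integers(lo, hi + 1))
        return GenomicInterval(config.chrom, start, start + length - 1)
    for _ in range(10_000):
        start = int(rng.integers(1, config.chrom_length - length + 2))
        iv = GenomicInterval(config.chrom, start, start + length - 1)
        if not any(intervals_overlap(iv, t) for t in targets):
            return iv
    raise RuntimeError("could not place a non-hit deletion; planted elements too dense")


def simulate_cohorts(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, list[CnvRecord]], dict[str, dict[str, bool]]]:
    """Draw the case and the two control deletion cohorts.

    Each patient contributes one deletion; with probability ``p_hit_case``
    (cases) or ``p_hit_control`` (controls) it overlaps a planted element.
    Lengths and log2 ratios respect the preprocessing filter by
    construction. Returns (cohorts, per-patient hit labels).
    """
    if rng is None:
        rng = _rng(config, "cohorts")
    cohorts: dict[str, list[CnvRecord]] = {}
    hits: dict[str, dict[str, bool]] = {}
    plan = [(CASE_COHORT, config.n_case, config.p_hit_case)] + [
        (name, config.n_control, config.p_hit_control) for name in CONTROL_COHORTS
    ]
    for cohort_name, n, p_hit in plan:
        records: list[CnvRecord] = []
        labels: dict[str, bool] = {}
        for i in range(n):
            pid = f"{cohort_name}-{i:03d}"
            hit = bool(rng.random() < p_hit)
            iv = _draw_deletion(rng, config, hit)
            l2r = round(float(rng.uniform(-1.5, -0.4)), 3)
            records.append(
                CnvRecord(
                    patient_id=pid,
                    interval=iv,
                    log2ratio=l2r,
                    state=DELETION,
                    cohort=cohort_name,
                )
            )
            labels[pid] = hit
        cohorts[cohort_name] = records
        hits[cohort_name] = labels
    return cohorts, hits


def _expected_tables(
    config: SyntheticConfig, hits: Mapping[str, Mapping[str, bool]]
) -> dict[str, dict[str, int]]:
    a = sum(hits[CASE_COHORT].values())
    b = config.n_case - a
    tables = {}
    for name in CONTROL_COHORTS:
        c = sum(hits[name].values())
        tables[f"case-vs-{name}"] = {"a": a, "b": b, "c": c, "d": config.n_control - c}
    return tables


def build_locus(config: SyntheticConfig) -> SyntheticLocus:
    """Assemble the full in-memory synthetic locus from a validated config."""
    config.validate()
    genome = _build_sequence(config)
    coverage = _build_coverage(config)
    peaks = _build_peaks(config)
    cage, tfbs = _build_cage_tfbs(config)
    junctions = _build_junctions(config)
    cohorts, hits = simulate_cohorts(config)
    truth = SyntheticTruth(
        elements=config.planted_elements,
        decoys=config.decoys,
        donor_contexts={
            el.name: genome.subseq(el.boundary_pos - 1, el.boundary_pos + 2)
            for el in config.planted_elements
        },
        acceptor_starts={
            el.name: config.gene.exons[el.acceptor_exon].start
            for el in config.planted_elements
        },
        patient_hits=hits,
        expected_tables=_expected_tables(config, hits),
    )
    return SyntheticLocus(
        config=config,
        genome=genome,
        gene=config.gene,
        coverage=coverage,
        peaks=peaks,
        cage=cage,
        tfbs=tfbs,
        junctions=junctions,
        cohorts=cohorts,
        truth=truth,
    )


def generate_dataset(config: SyntheticConfig, outdir) -> SyntheticTruth:
    """Write the complete synthetic dataset to ``outdir`` and return the truth.

    Outputs: genome FASTA, gene model BED12, per-marker narrowPeak files,
    CAGE BED, TFBS BED, per-base coverage bedGraph, junction TSV, one cohort
    TSV per cohort, ``truth.json`` and a ``manifest.json`` of sha256
    checksums. Identical seeds give byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    locus = build_locus(config)

    write_fasta(outdir / "genome.fa", [locus.genome])
    write_gene_model_bed12(outdir / "gene_model.bed12", [locus.gene])
    markers = sorted({p.marker for p in locus.peaks})
    for marker in markers:
        write_narrowpeak(
            outdir / f"peaks_{marker}.narrowPeak",
            [p for p in locus.peaks if p.marker == marker],
        )
    write_cage_bed(outdir / "cage.bed", locus.cage)
    write_bed(outdir / "tfbs.bed", [BedRecord(t, name=f"tfbs:{i}") for i, t in enumerate(locus.tfbs)])
    write_bedgraph(outdir / "coverage.bedGraph", locus.coverage)
    write_junctions_tsv(outdir / "junctions.tsv", locus.junctions)
    for name, records in locus.cohorts.items():
        write_cohort_tsv(outdir / f"cohort_{name}.tsv", records)
    (outdir / "truth.json").write_text(json.dumps(locus.truth.to_jsonable(), indent=1, sort_keys=True))

    manifest = {}
    for f in sorted(outdir.iterdir()):
        if f.name == "manifest.json" or f.is_dir():
            continue
        manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return locus.truth
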