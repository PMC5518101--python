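"""Readers and writers for the standard text formats the pipeline consumes.

Coordinate contract: BED-family formats (BED, narrowPeak, bedGraph) are
0-based half-open on disk and are converted to the package-internal 1-based
inclusive convention on read; writers invert the conversion, so a
write-then-read round trip is the identity.

Cohort tables, junction tables and candidate tables are plain TSV handled
with pandas. FASTA goes through Bio.SeqIO.
"""

from __future__ import annotations


from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .cohort import CnvRecord
from .intervals import GenomicInterval, SequenceRecord
from .promoter import CagePeak, PeakRecord
from .splicing import CoverageTrack, JunctionRecord

__all__ = [
    "FileFormatError",
    "BedRecord",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bedgraph",
    "write_bedgraph",
    "read_cage_bed",
    "write_cage_bed",
    "read_cohort_tsv",
    "write_cohort_tsv",
    "read_junctions_tsv",
    "write_junctions_tsv",
    "read_fasta",
    "write_fasta",
    "read_gene_model_bed12",
    "write_gene_model_bed12",
]

COHORT_COLUMNS = [
    "patient_id",
    "chrom",
    "start",
    "end",
    "log2ratio",
    "state",
    "cohort",
    "inheritance",
    "phenotype",
]


class FileFormatError(ValueError):
    """A malformed line in a track/table file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _bed_to_internal(path, lineno: int, chrom: str, start0: str, end0: str) -> GenomicInterval:
    try:
        s, e = int(start0), int(end0)
    except ValueError as exc:
        raise FileFormatError(path, lineno, f"non-integer coordinates: {exc}") from None
    if s < 0 or e <= s:
        raise FileFormatError(path, lineno, f"bad half-open interval [{s}, {e})")
    return GenomicInterval(chrom, s + 1, e)


def _data_lines(path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


@dataclass(frozen=True)
class BedRecord:
    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    strand: str = "."


def read_bed(path) -> list[BedRecord]:
    """Read BED3/BED6 into 1-based inclusive records."""
    out = []
    for lineno, f in _data_lines(path):
        if len(f) < 3:
            raise FileFormatError(path, lineno, f"expected >=3 BED columns, got {len(f)}")
        iv = _bed_to_internal(path, lineno, f[0], f[1], f[2])
        name = f[3] if len(f) > 3 else "."
        score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
        strand = f[5] if len(f) > 5 else "."
        out.append(BedRecord(iv, name, score, strand))
    return out


def write_bed(path, records: Iterable[BedRecord | GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for r in records:
            if isinstance(r, GenomicInterval):
                r = BedRecord(r)
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{r.name}\t{r.score:g}\t{r.strand}\n"
            )


def read_narrowpeak(path, marker: str | None = None, tissue: str | None = None) -> list[PeakRecord]:
    """Read ENCODE narrowPeak (BED6 + signalValue, pValue, qValue, peak).

    ``marker``/``tissue`` label every peak in the file; when omitted they are
    parsed from the name column, expected as ``marker:tissue[:suffix]``.
    """
    out = []
    for lineno, f in _data_lines(path):
        if len(f) < 10:
            raise FileFormatError(path, lineno, f"expected 10 narrowPeak columns, got {len(f)}")
        iv = _bed_to_internal(path, lineno, f[0], f[1], f[2])
        m, t = marker, tissue
        if m is None or t is None:
            parts = f[3].split(":")
            if len(parts) < 2:
                raise FileFormatError(
                    path, lineno, f"cannot infer marker/tissue from name {f[3]!r}"
                )
            m = m or parts[0]
            t = t or parts[1]
        try:
            signal = float(f[6])
            neglog10p = float(f[7])
        except ValueError as exc:
            raise FileFormatError(path, lineno, f"bad signal/p column: {exc}") from None
        out.append(PeakRecord(iv, marker=m, tissue=t, signal=signal, neglog10p=neglog10p))
    return out


def write_narrowpeak(path, peaks: Iterable[PeakRecord]) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{p.marker}:{p.tissue}:{i}\t0\t.\t"
                f"{p.signal:g}\t{p.neglog10p:g}\t-1\t-1\n"
            )


def read_bedgraph(path, chrom: str | None = None) -> CoverageTrack:
    """Expand a 4-column bedGraph into a per-base depth track.

    The file must describe a single chromosome (or ``chrom`` selects one);
    bases not covered by any record get depth 0.
    """
    spans: list[tuple[int, int, int]] = []
    seen_chrom: str | None = None
    for lineno, f in _data_lines(path):
        if len(f) < 4:
            raise FileFormatError(path, lineno, f"expected 4 bedGraph columns, got {len(f)}")
        if chrom is not None and f[0] != chrom:
            continue
        if seen_chrom is None:
            seen_chrom = f[0]
        elif f[0] != seen_chrom:
            raise FileFormatError(
                path, lineno, f"multiple chromosomes ({seen_chrom}, {f[0]}); pass chrom="
            )
        iv = _bed_to_internal(path, lineno, f[0], f[1], f[2])
        try:
            depth = int(round(float(f[3])))
        except ValueError as exc:
            raise FileFormatError(path, lineno, f"bad depth column: {exc}") from None
        if depth < 0:
            raise FileFormatError(path, lineno, f"negative depth {depth}")
        spans.append((iv.start, iv.end, depth))
    if not spans:
        raise FileFormatError(path, 0, f"no bedGraph records for chrom {chrom!r}")
    origin = min(s for s, _, _ in spans)
    extent = max(e for _, e, _ in spans)
    depth = np.zeros(extent - origin + 1, dtype=np.int64)
    for s, e, d in spans:
        depth[s - origin : e - origin + 1] = d
    return CoverageTrack(chrom=seen_chrom, origin=origin, depth=depth)


def write_bedgraph(path, track: CoverageTrack) -> None:
    """Run-length encode a per-base track back into bedGraph (0-depth runs kept)."""
    with open(path, "w") as fh:
        depth = track.depth
        run_start = 0
        for i in range(1, len(depth) + 1):
            if i == len(depth) or depth[i] != depth[run_start]:
                start1 = track.origin + run_start
                end1 = track.origin + i - 1
                fh.write(f"{track.chrom}\t{start1 - 1}\t{end1}\t{int(depth[run_start])}\n")
                run_start = i


def read_cage_bed(path) -> list[CagePeak]:
    """CAGE peaks as BED6 plus a 7th column ``tissue=tpm,tissue=tpm,...``."""
    out = []
    for lineno, f in _data_lines(path):
        if len(f) < 7:
            raise FileFormatError(path, lineno, f"expected 7 CAGE columns, got {len(f)}")
        iv = _bed_to_internal(path, lineno, f[0], f[1], f[2])
        strand = f[5]
        expression = {}
        for pair in f[6].split(","):
            if not pair:
                continue
            try:
                tissue, tpm = pair.split("=")
                expression[tissue] = float(tpm)
            except ValueError:
                raise FileFormatError(path, lineno, f"bad expression field {pair!r}") from None
        out.append(CagePeak(interval=iv, strand=strand, expression=expression))
    return out


def write_cage_bed(path, peaks: Iterable[CagePeak]) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            expr = ",".join(f"{t}={v:g}" for t, v in sorted(p.expression.items()))
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\tcage:{i}\t0\t{p.strand}\t{expr}\n")


def read_cohort_tsv(path) -> list[CnvRecord]:
    """Read a CNV cohort table (header required, 1-based inclusive coordinates).

    Columns: patient_id, chrom, start, end, log2ratio, state, cohort,
    inheritance, phenotype. ``log2ratio`` may be empty (categorical sources);
    ``state`` may be empty when a log2ratio is present, in which case it is
    derived from the sign.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(path, 1, f"missing cohort columns {missing}")
    out = []
    for idx, row in df.iterrows():
        lineno = int(idx) + 2  # header is line 1
        try:
            iv = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
        except ValueError as exc:
            raise FileFormatError(path, lineno, str(exc)) from None
        l2r = None if row["log2ratio"] == "" else float(row["log2ratio"])
        state = row["state"] or None
        try:
            rec = CnvRecord(
                patient_id=row["patient_id"],
                interval=iv,
                log2ratio=l2r,
                state=state,
                cohort=row["cohort"],
                inheritance=row["inheritance"] or None,
                phenotype=row["phenotype"] or None,
            )
        except ValueError as exc:
            raise FileFormatError(path, lineno, str(exc)) from None
        out.append(rec)
    return out


def write_cohort_tsv(path, records: Iterable[CnvRecord]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "log2ratio": "" if r.log2ratio is None else repr(r.log2ratio),
                "state": r.state,
                "cohort": r.cohort,
                "inheritance": r.inheritance or "",
                "phenotype": r.phenotype or "",
            }
        )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, sep="\t", index=False)


JUNCTION_COLUMNS = ["chrom", "donor_pos", "acceptor_pos", "read_count", "strand"]


def read_junctions_tsv(path) -> list[JunctionRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in JUNCTION_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(path, 1, f"missing junction columns {missing}")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                JunctionRecord(
                    chrom=row["chrom"],
                    donor_pos=int(row["donor_pos"]),
                    acceptor_pos=int(row["acceptor_pos"]),
                    read_count=int(row["read_count"]),
                    strand=row["strand"],
                )
            )
        except ValueError as exc:
            raise FileFormatError(path, int(idx) + 2, str(exc)) from None
    return out


def write_junctions_tsv(path, junctions: Iterable[JunctionRecord]) -> None:
    rows = [
        {
            "chrom": j.chrom,
            "donor_pos": j.donor_pos,
            "acceptor_pos": j.acceptor_pos,
            "read_count": j.read_count,
            "strand": j.strand,
        }
        for j in junctions
    ]
    pd.DataFrame(rows, columns=JUNCTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, SequenceRecord]:
    return {
        rec.id: SequenceRecord(name=rec.id, seq=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path, records: Iterable[SequenceRecord]) -> None:
    bio = [BioSeqRecord(Seq(r.seq), id=r.name, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene model: ordered exons on one strand."""

    name: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("gene model needs >= 1 exon")
        starts = [e.start for e in self.exons]
        if starts != sorted(starts):
            raise ValueError("exons must be sorted by genomic position")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end + 1:
                out.append(GenomicInterval(self.chrom, a.end + 1, b.start - 1))
        return out


def read_gene_model_bed12(path) -> list[GeneModel]:
    out = []
    for lineno, f in _data_lines(path):
        if len(f) < 12:
            raise FileFormatError(path, lineno, f"expected 12 BED12 columns, got {len(f)}")
        span = _bed_to_internal(path, lineno, f[0], f[1], f[2])
        strand = f[5]
        n = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != n or len(offsets) != n:
            raise FileFormatError(path, lineno, "blockCount disagrees with block lists")
        exons = tuple(
            GenomicInterval(f[0], span.start + off, span.start + off + size - 1)
            for off, size in zip(offsets, sizes)
        )
        out.append(GeneModel(name=f[3], chrom=f[0], strand=strand, exons=exons))
    return out


def write_gene_model_bed12(path, models: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        for m in models:
            span = m.span
            sizes = ",".join(str(e.width) for e in m.exons)
            offsets = ",".join(str(e.start - span.start) for e in m.exons)
            fh.write(
                f"{m.chrom}\t{span.start - 1}\t{span.end}\t{m.name}\t0\t{m.strand}\t"
                f"{span.start - 1}\t{span.end}\t0\t{len(m.exons)}\t{sizes}\t{offsets}\n"
            )
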