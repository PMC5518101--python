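"""Packaged DLG2 locus fixture.

The bundle carries the published 29-patient deletion cohort over the DLG2
7-9 region (hg19), the HPin7/HPin8 candidate regions with their coding
first exons, the GDD/ID validation-cohort contingency counts, and the
printed reference values the reproduction report checks itself against.
Everything is data as printed; all derived numbers (overlap counts, p
values, widths) are recomputed by the pipeline at run time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

from .cohort import CnvRecord, DELETION, FeatureSet
from .enrichment import ContingencyTable
from .intervals import GenomicInterval

__all__ = ["Dlg2Fixture", "dlg2_fixture", "DLG2_CASE_COHORT"]

DLG2_CASE_COHORT = "dlg2-case"


@dataclass(frozen=True)
class Dlg2Fixture:
    patients: tuple[CnvRecord, ...]
    features: FeatureSet
    hpin7: GenomicInterval
    hpin8: GenomicInterval
    cfein7: GenomicInterval
    cfein8: GenomicInterval
    strand: str
    candidate_rows: Mapping[str, Mapping]
    splice_boundaries: Mapping[str, Mapping]
    gddid_counts: Mapping[str, int]
    reference_values: Mapping[str, float]

    def gddid_table(self) -> ContingencyTable:
        """2x2 table for GDD/ID cases vs controls, any-HP deletion."""
        g = self.gddid_counts
        return ContingencyTable(
            a=g["case_hp"],
            b=g["case_total"] - g["case_hp"],
            c=g["control_hp"],
            d=g["control_total"] - g["control_hp"],
        )


def _data_text(name: str) -> str:
    return resources.files("cfescan.data").joinpath(name).read_text()


def dlg2_fixture() -> Dlg2Fixture:
    """Load the packaged DLG2 fixture bundle."""
    import io as _io

    df = pd.read_csv(_io.StringIO(_data_text("dlg2_patients.tsv")), sep="\t", dtype=str)
    patients = tuple(
        CnvRecord(
            patient_id=row["patient_id"],
            interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
            log2ratio=None,
            state=DELETION,
            cohort=DLG2_CASE_COHORT,
            inheritance=row["inheritance"],
            phenotype=row["phenotype"],
        )
        for _, row in df.iterrows()
    )

    elements = json.loads(_data_text("dlg2_elements.json"))
    ivs = {
        name: GenomicInterval(e["chrom"], e["start"], e["end"])
        for name, e in elements["elements"].items()
    }
    counts = json.loads(_data_text("dlg2_counts.json"))
    return Dlg2Fixture(
        patients=patients,
        features=FeatureSet(ivs),
        hpin7=ivs["HPin7"],
        hpin8=ivs["HPin8"],
        cfein7=ivs["CFEin7_coding"],
        cfein8=ivs["CFEin8_coding"],
        strand=elements["strand"],
        candidate_rows=elements["candidate_rows"],
        splice_boundaries=elements["splice_boundaries"],
        gddid_counts=counts["gddid"],
        reference_values=counts["reference_values"],
    )
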