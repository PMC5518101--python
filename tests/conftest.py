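import glob

import pytest

from cfescan.fixtures import dlg2_fixture
from cfescan.intervals import GenomicInterval
from cfescan.pipeline import PipelineConfig
from cfescan.simulate import build_locus, default_config, generate_dataset


@pytest.fixture(scope="session")
def dlg2():
    return dlg2_fixture()


@pytest.fixture(scope="session")
def locus():
    """The default synthetic locus (seed 1), fully in memory."""
    return build_locus(default_config(1))


@pytest.fixture(scope="session")
def synth_dir(tmp_path_factory):
    """The same locus written to disk as the standard text formats."""
    out = tmp_path_factory.mktemp("synth")
    generate_dataset(default_config(1), out)
    return out


@pytest.fixture
def synth_pipeline_config(synth_dir):
    return PipelineConfig(
        cohort_paths=sorted(glob.glob(str(synth_dir / "cohort_*.tsv"))),
        peak_paths=sorted(glob.glob(str(synth_dir / "peaks_*.narrowPeak"))),
        cage_path=str(synth_dir / "cage.bed"),
        tfbs_path=str(synth_dir / "tfbs.bed"),
        coverage_path=str(synth_dir / "coverage.bedGraph"),
        junctions_path=str(synth_dir / "junctions.tsv"),
        gene_model_path=str(synth_dir / "gene_model.bed12"),
        genome_path=str(synth_dir / "genome.fa"),
        universe=GenomicInterval("chrS", 1, 100_000),
        tissue="fetal_brain",
    )
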