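import numpy as np
import pytest

from clipnmd.synthetic_data import SimulationConfig, generate_genome


def small_config(**overrides) -> SimulationConfig:
    """Scaled-down study conditions for fast unit tests."""
    base = dict(
        n_genes=12, n_nmd_suppressed=3, n_nmd_promoted=2,
        tags_per_experiment=800, n_background_genes=100,
        intergenic_len=(12000, 13000),
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_genome(small_config(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


TOY_GFF3 = """\
##gff-version 3
chr1\ttoy\tgene\t101\t700\t.\t+\t.\tID=gA;cds_start=20;cds_end=260
chr1\ttoy\tmRNA\t101\t700\t.\t+\t.\tID=gA.t1;Parent=gA
chr1\ttoy\texon\t101\t250\t.\t+\t.\tID=gA.e01;Name=e01;Parent=gA.t1;exon_kind=constitutive
chr1\ttoy\texon\t401\t520\t.\t+\t.\tID=gA.e02;Name=e02;Parent=gA.t1;exon_kind=annotated-alternative
chr1\ttoy\texon\t601\t700\t.\t+\t.\tID=gA.e03;Name=e03;Parent=gA.t1;exon_kind=constitutive
chr1\ttoy\tgene\t1001\t1600\t.\t-\t.\tID=gB;cds_start=30;cds_end=330
chr1\ttoy\tmRNA\t1001\t1600\t.\t-\t.\tID=gB.t1;Parent=gB
chr1\ttoy\texon\t1001\t1200\t.\t-\t.\tID=gB.e01;Name=e01;Parent=gB.t1;exon_kind=constitutive
chr1\ttoy\texon\t1401\t1600\t.\t-\t.\tID=gB.e02;Name=e02;Parent=gB.t1;exon_kind=constitutive
chr2\ttoy\tgene\t51\t350\t.\t+\t.\tID=gC;cds_start=10;cds_end=220
chr2\ttoy\tmRNA\t51\t350\t.\t+\t.\tID=gC.t1;Parent=gC
chr2\ttoy\texon\t51\t350\t.\t+\t.\tID=gC.e01;Name=e01;Parent=gC.t1;exon_kind=constitutive
"""


@pytest.fixture()
def toy_gff3(tmp_path):
    p = tmp_path / "toy.gff3"
    p.write_text(TOY_GFF3)
    return p
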