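import numpy as np
import pytest

from svlink.annotate import GeneModel, GeneModelSet
from svlink.simulate import SimConfig, make_gene_models, simulate_sv_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=5, n_chroms=1, chrom_length_bp=1_000_000,
                     n_genes=60, n_sv=200, n_divergent_sv=10)


@pytest.fixture(scope="session")
def small_models(small_config):
    return make_gene_models(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_models, small_config):
    return simulate_sv_cohort(small_models, small_config)


@pytest.fixture()
def toy_models() -> GeneModelSet:
    """Two hand-built genes (one per strand) with room around them."""
    plus = GeneModel(
        gene_id="gPlus", chrom="chr1", strand="+",
        tx_start=10_000, tx_end=13_000,
        exons=((10_000, 10_800), (11_500, 12_200), (12_600, 13_000)),
        cds=((10_150, 10_800), (11_500, 12_200), (12_600, 12_900)),
        utr5=((10_000, 10_149),),
        utr3=((12_901, 13_000),),
    )
    minus = GeneModel(
        gene_id="gMinus", chrom="chr1", strand="-",
        tx_start=40_000, tx_end=43_000,
        exons=((40_000, 40_700), (41_400, 42_100), (42_500, 43_000)),
        cds=((40_100, 40_700), (41_400, 42_100), (42_500, 42_850)),
        utr5=((42_851, 43_000),),
        utr3=((40_000, 40_099),),
    )
    return GeneModelSet([plus, minus])


class FakeSV:
    """Minimal stand-in for classify_sv inputs."""

    def __init__(self, id, chrom, start, end, svtype="DEL"):
        self.id = id
        self.chrom = chrom
        self.start = start
        self.end = end
        self.svtype = svtype


@pytest.fixture()
def fake_sv():
    return FakeSV
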