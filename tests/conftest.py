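import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from svselect import GeneModel, GenomeDef  # noqa: E402


@pytest.fixture
def small_genome():
    return GenomeDef.uniform(3, 10_000_000)


@pytest.fixture
def toy_gene():
    return GeneModel(
        symbol="TSG1",
        transcript="T1",
        chrom="chr1",
        strand="+",
        exons=[(100_000, 100_500), (200_000, 200_300), (300_000, 300_200)],
        cancer_gene=True,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
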