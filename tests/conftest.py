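import numpy as np
import pytest

from tetrapop.synthetic_data import GeneFeature, GeneModel, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20120)


@pytest.fixture
def small_gene():
    """A 1.2 kb two-exon gene with one intron, CDS length divisible by 3."""
    return GeneModel(
        gene_id="geneA",
        length=1200,
        features=[
            GeneFeature(0, 450, "CDS", 0),
            GeneFeature(450, 600, "intron"),
            GeneFeature(600, 1200, "CDS", 0),
        ],
    )


@pytest.fixture
def sim_config():
    return SimConfig(seed=1)
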