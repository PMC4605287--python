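import numpy as np
import pytest

from ambarcode import PSFModel, find_motif_sites, load_genome


@pytest.fixture(scope="session")
def lambda_genome():
    return load_genome("lambda")


@pytest.fixture(scope="session")
def t7_genome():
    return load_genome("t7")


@pytest.fixture(scope="session")
def lambda_sites(lambda_genome):
    return find_motif_sites(lambda_genome, "TCGA")


@pytest.fixture(scope="session")
def psf():
    return PSFModel(fwhm_bp=1500.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
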