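import pytest

from crispraid.pipeline import DesignConfig, design_library
from crispraid.synthetic_data import SimConfig, make_toy_genome


@pytest.fixture(scope="session")
def toy():
    """20-gene single-contig toy genome, fixed seed."""
    config = SimConfig(seed=7, n_genes=20)
    return make_toy_genome(config)


@pytest.fixture(scope="session")
def toy_genome(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_features(toy):
    return toy[1]


@pytest.fixture(scope="session")
def designed(toy):
    """Full three-library design on the toy genome (manifest + oligos)."""
    genome, features = toy
    return design_library(genome, features, DesignConfig(seed=7))


@pytest.fixture(scope="session")
def manifest(designed):
    return designed.manifest
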