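import numpy as np
import pytest

from rps12evo.synthetic_data import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """8-taxon standard-layout bundle with one type-II clade."""
    return simulate_bundle(SimConfig(seed=42, n_taxa=8, typeII_clades=[3]))


@pytest.fixture(scope="session")
def default_bundle():
    """16-taxon bundle mirroring the study layout (124 codons, two type-II
    clades)."""
    return simulate_bundle(SimConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
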