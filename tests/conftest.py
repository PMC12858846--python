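import numpy as np
import pytest

from psvkit import SimConfig, simulate_scenario


@pytest.fixture(scope="session")
def small_bundle():
    """A small heterozygous-variant scenario shared by read-level tests."""
    return simulate_scenario(SimConfig(seed=11, gene_length=2000))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
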