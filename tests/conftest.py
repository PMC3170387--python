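import numpy as np
import pytest

from plastokit import simulate_plastome


@pytest.fixture(scope="session")
def small_plastome():
    """Scaled-down plastome (16.2 kb total, segments 9000/3100/1000/3100)."""
    return simulate_plastome(size_factor=0.1, gene_count=20, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
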