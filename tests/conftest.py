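import numpy as np
import pytest

from pheseq import RunConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def tiny_dataset():
    """40 genes, 6 embedding dims — enough structure for fast unit tests."""
    return simulate_dataset(G=40, D=6, frac_assoc=0.25, seed=5)


@pytest.fixture
def small_config():
    return RunConfig(mode="static", seed=7, max_iters=50, posterior_sweeps=10)
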