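import numpy as np
import pytest

from droughtfire import synthetic


@pytest.fixture(scope="session")
def grid5():
    return synthetic.gen_grid(5, 5, seed=11)


@pytest.fixture(scope="session")
def grid10():
    return synthetic.gen_grid(10, 10, seed=7)


@pytest.fixture(scope="session")
def climate30(grid5):
    """30 years of monthly climate on the 5x5 grid (trend-free)."""
    return synthetic.gen_climate(grid5, years=30, trend=0.0, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
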