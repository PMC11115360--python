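import numpy as np
import pytest

from absampler.hypothesis_model import discrete_grid, gaussian


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def unit_gaussian():
    return gaussian(0.0, 1.0)


@pytest.fixture
def numerosity_posterior():
    """The running example: posterior over dot counts after seeing ~24 dots."""
    return gaussian(24.0, 3.0)


@pytest.fixture
def five_cell_posterior():
    """Small tabulated posterior whose exact probabilities are known."""
    mass = np.array([0.1, 0.25, 0.3, 0.2, 0.15])
    return discrete_grid(np.arange(5.0), np.log(mass))
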