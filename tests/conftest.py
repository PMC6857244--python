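import numpy as np
import pytest

from bandclust import BandSimilarity


def random_band(p, h, rng, low=-1.0, high=1.0):
    """Random banded similarity with mixed-sign values."""
    band = rng.uniform(low, high, (p, h))
    for d in range(1, h):
        band[p - d:, d] = 0
    return BandSimilarity(band)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_band():
    return random_band
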