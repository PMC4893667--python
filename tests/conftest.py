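import numpy as np
import pytest

from osessl import make_blobs, make_swiss_roll
from osessl.affinity import from_values


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_blobs():
    """Three well-separated Gaussian clusters, 60 points."""
    return make_blobs([20, 30, 10], separation=6.0, seed=7)


@pytest.fixture
def small_roll():
    """A 300-point two-class Swiss Roll with mild noise."""
    return make_swiss_roll(300, 2, noise_sd=0.25, seed=3)


def random_dissimilarity(rng, n, scale=1.0):
    """A valid random dissimilarity matrix (symmetric, zero diagonal)."""
    points = rng.random((n, 3)) * scale
    from scipy.spatial.distance import cdist

    return from_values(cdist(points, points))
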