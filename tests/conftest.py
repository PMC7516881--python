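import numpy as np
import pytest

from gaussfr import Gaussian, make_gaussian
from gaussfr.synthetic import random_spd


EXAMPLE1_SIGMA = [[1.1, 0.9], [0.9, 1.1]]


@pytest.fixture
def example1_pair():
    """Bivariate pair with common covariance [[1.1,.9],[.9,1.1]], means (-1,0),(6,3)."""
    return (
        make_gaussian([-1.0, 0.0], EXAMPLE1_SIGMA),
        make_gaussian([6.0, 3.0], EXAMPLE1_SIGMA),
    )


@pytest.fixture
def mirrored_sigmas():
    """The bivariate mirrored covariances with eigenvalues {1, 0.1}."""
    return (
        np.array([[0.55, -0.45], [-0.45, 0.55]]),
        np.array([[0.55, 0.45], [0.45, 0.55]]),
    )


def random_gaussian(n: int, seed: int, mean_scale: float = 1.0) -> Gaussian:
    rng = np.random.default_rng(seed)
    return Gaussian(mean_scale * rng.standard_normal(n), random_spd(n, seed + 991))


@pytest.fixture
def gaussian_factory():
    return random_gaussian
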