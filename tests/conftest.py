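import numpy as np
import pytest

from noisefbn import center_normalize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_normalized(rng):
    """A 30 x 8 centered, unit-norm time-series matrix."""
    return center_normalize(rng.standard_normal((30, 8)))


def random_spd(rng, n, scale=1.0):
    A = rng.standard_normal((n, n))
    return scale * (A @ A.T + n * np.eye(n))
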