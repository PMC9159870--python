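import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    return rng.random((16, 16))


@pytest.fixture
def smooth_image(rng):
    """A speckle-free smooth field, safe from interpolation ties."""
    from scipy import ndimage

    return ndimage.gaussian_filter(rng.standard_normal((32, 32)), 2.0)
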