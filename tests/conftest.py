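import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_image():
    """A deterministic 16x16 nonnegative image with 1 mm pixels."""
    from hypersi import MagnitudeImage

    g = np.random.default_rng(7)
    return MagnitudeImage(g.random((16, 16)), (1.0, 1.0))
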