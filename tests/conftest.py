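import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def feature_map(rng):
    """A small random (batch, channel, height, width) feature map."""
    return rng.normal(size=(2, 8, 6, 5))
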