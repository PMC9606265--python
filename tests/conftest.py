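import numpy as np
import pytest

from engram import synthetic as sy


@pytest.fixture(scope="session")
def small_mask():
    """256 x 256 two-blade mask, 1 µm pixels."""
    return sy.make_layer_mask(256, 256, 1.0, seed=1)


@pytest.fixture(scope="session")
def large_mask():
    """1024 x 1024 two-blade mask used for cluster analyses."""
    return sy.make_layer_mask(1024, 1024, 1.0, sy.BandParams(thickness_px=48), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
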