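import numpy as np
import pytest

from octarep.images import DeviceProfile, GrayImage


@pytest.fixture
def bench_profile():
    """Small raster profile used throughout the suite (3 mm field)."""
    return DeviceProfile("bench", 128)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def random_image(rng):
    return GrayImage(rng.integers(0, 256, (64, 64)).astype(np.uint8), 10.0)
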