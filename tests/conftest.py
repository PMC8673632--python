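import numpy as np
import pytest

from voxelseg import build_pyramid
from voxelseg.synth import make_three_region_volume
from voxelseg.volume import Volume


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_volume():
    """Seeded random uint16 volume, 20^3."""
    r = np.random.default_rng(7)
    return Volume(r.integers(0, 65536, size=(20, 20, 20), dtype=np.uint16))


@pytest.fixture(scope="session")
def small_pyramid(small_volume):
    return build_pyramid(small_volume, 1)


@pytest.fixture(scope="session")
def textured_20():
    """Three-region 20^3 labelled fixture (volume, labels, label_map)."""
    return make_three_region_volume((20, 20, 20), seed=11)


@pytest.fixture(scope="session")
def textured_32():
    return make_three_region_volume((32, 32, 32), seed=5)
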