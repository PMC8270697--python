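import numpy as np
import pytest

from virtstain import synthetic
from virtstain.types import ImageTile, STAINED, UNSTAINED


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stained():
    tiles, _ = synthetic.geometry_tiles(4, 32, seed=11, domain=STAINED)
    return tiles


@pytest.fixture
def small_unstained():
    tiles, _ = synthetic.geometry_tiles(4, 32, seed=22, domain=UNSTAINED)
    return tiles


@pytest.fixture
def tiny_pairs():
    return synthetic.paired_tiles(2, 32, seed=5)


def make_tile(arr, domain=STAINED, value_range=(0.0, 1.0)):
    return ImageTile(np.asarray(arr, dtype=float), domain, value_range)


@pytest.fixture
def ramp_tile():
    h = w = 8
    arr = np.linspace(0, 1, h * w * 3).reshape(h, w, 3)
    return make_tile(arr)
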