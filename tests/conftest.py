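import numpy as np
import pytest

from sloquant.imgio import FundusImage, ImageMeta
from sloquant.measure import ProtocolConfig

#: protocol configuration used for planted-truth recovery benchmarks:
#: triangle auto threshold, particle floor just below the smallest planted
#: soma (radius 2 px -> ~13 px), everything else at defaults
BENCHMARK_CONFIG = ProtocolConfig(min_area_px=10)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_image():
    """Wrap a float array into a preprocessed-domain FundusImage."""

    def _make(arr, bit_depth=None, **meta_kw):
        return FundusImage(np.asarray(arr), bit_depth=bit_depth,
                           meta=ImageMeta(meta_kw.pop("animal_id", "t01"),
                                          **meta_kw))

    return _make


@pytest.fixture
def random_masks(rng):
    """Factory: n random boolean masks of a given shape and density."""

    def _make(n, shape=(32, 32), density=0.35):
        return [rng.uniform(size=shape) < density for _ in range(n)]

    return _make
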