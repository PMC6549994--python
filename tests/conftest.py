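import numpy as np
import pytest

from landmarkov import CategoricalRaster, ContinuousRaster, GridTransform, Legend

TRANSFORM_25M = GridTransform(0.0, 1000.0, 25.0)


@pytest.fixture
def transform():
    return TRANSFORM_25M


@pytest.fixture
def legend3():
    return Legend([(1, "forest"), (2, "grass"), (3, "urban")])


def make_cat(values, nodata=-9999, transform=TRANSFORM_25M, legend=None, crs="test"):
    values = np.asarray(values)
    t = GridTransform(0.0, values.shape[0] * transform.pixel_size, transform.pixel_size)
    return CategoricalRaster(values, nodata, t, crs, legend)


def make_cont(values, transform=TRANSFORM_25M, mask=None, crs="test"):
    values = np.asarray(values, dtype=float)
    t = GridTransform(0.0, values.shape[0] * transform.pixel_size, transform.pixel_size)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    return ContinuousRaster(values, mask, t, crs)


@pytest.fixture
def pair_2x2(legend3):
    """The enumeration-oracle fixture: t1=[[1,1],[2,2]], t2=[[1,2],[2,2]]."""
    t1 = make_cat([[1, 1], [2, 2]], legend=legend3)
    t2 = make_cat([[1, 2], [2, 2]], legend=legend3)
    return t1, t2
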