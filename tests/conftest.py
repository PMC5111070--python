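import numpy as np
import pandas as pd
import pytest

from carniplan.raster import ClassMap, Raster


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_raster(values, cell_km=1.0, origin=(0.0, 0.0)):
    return Raster(np.asarray(values, dtype=float), cell_km, origin)


def make_class_map(codes, cell_km=1.0, origin=(0.0, 0.0)):
    return ClassMap(np.asarray(codes, dtype=int), cell_km, origin)


def records_frame(points):
    xs, ys = zip(*points) if points else ((), ())
    return pd.DataFrame({"x_km": xs, "y_km": ys, "date": "2012-01-01", "source": "t"})


@pytest.fixture
def uniform_raster():
    """10 x 10 km raster, all cells 0.6."""
    return make_raster(np.full((10, 10), 0.6))
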