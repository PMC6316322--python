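import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from monarchniche.grids import Grid, LayerName, LayerStack
from monarchniche.synthetic import benchmark_dataset


def make_grid(values, cellsize=1.0, xll=0.0, yll=0.0, nodata=-9999.0):
    values = np.asarray(values, dtype=float)
    return Grid(values.shape[1], values.shape[0], xll, yll, cellsize,
                nodata, values)


def make_stack(**named_values):
    """LayerStack from keyword arrays, e.g. tmin_Jan=[[...]]."""
    return LayerStack({LayerName.parse(k): make_grid(v)
                       for k, v in named_values.items()})


@pytest.fixture(scope="session")
def small_benchmark():
    """A 40x40 synthetic study, shared (read-only) across tests."""
    return benchmark_dataset(seed=7, nrows=40, ncols=40, n_groves=60)


@pytest.fixture(scope="session")
def small_presences(small_benchmark):
    from monarchniche.occurrences import thin
    d = small_benchmark
    occ = thin(d.records, d.current)
    g = d.current.grid
    return np.array(sorted({g.flat_index(lon, lat) for lon, lat in occ.points}),
                    dtype=int)
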