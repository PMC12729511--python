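import numpy as np
import pandas as pd
import pytest

from qregions.occurrences import OccurrenceSet, assemble_design
from qregions.raster import GridSpec, RasterGrid, RasterStack
from qregions.synth import SyntheticScenario, generate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """One realization of the default synthetic scenario, shared across the
    suite (the generator is deterministic under the seed)."""
    return generate_bundle(SyntheticScenario(seed=1))


@pytest.fixture(scope="session")
def default_design(default_bundle):
    return assemble_design(OccurrenceSet(default_bundle.presences),
                           default_bundle.env, background_n=10000, seed=7)


@pytest.fixture(scope="session")
def small_bundle():
    """A 40x40 desk-size scenario for cheap unit tests."""
    sc = SyntheticScenario(seed=5)
    sc.spec = GridSpec(n_rows=40, n_cols=40, x_min=106.0, y_max=31.0,
                       dx=0.05, dy=0.05)
    sc.occurrence_n = 60
    return generate_bundle(sc)


@pytest.fixture()
def tiny_stack():
    """3x4 two-layer stack with one nodata cell, for extraction tests."""
    spec = GridSpec(n_rows=3, n_cols=4, x_min=100.0, y_max=30.0, dx=0.5, dy=0.5)
    a = np.arange(12, dtype=float).reshape(3, 4)
    b = a * 10.0
    b[1, 1] = np.nan
    return RasterStack({"a": RasterGrid(spec, a), "b": RasterGrid(spec, b)})
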