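import numpy as np
import pytest

import redose as rd


@pytest.fixture
def small_geom():
    """Tiny axis-aligned 1 mm grid for unit tests."""
    return rd.GridGeometry(origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0),
                           shape=(10, 10, 6), frame_id="unit")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def example_bundle():
    return rd.make_worked_example_case()


@pytest.fixture(scope="session")
def example_accum(example_bundle):
    """Accumulated worked-example case with the default alpha/beta map."""
    return rd.accumulate(
        example_bundle.courses,
        example_bundle.geometry,
        list(example_bundle.structures.values()),
        rd.AlphaBetaMap(),
    )


def uniform_grid(geom, value, kind=rd.DoseKind.PHYSICAL):
    return rd.DoseGrid(geometry=geom, values=np.full(geom.shape, float(value)),
                       dose_kind=kind)


@pytest.fixture
def make_uniform():
    return uniform_grid
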