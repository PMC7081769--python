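import numpy as np
import pytest

from gfcdmap import synth
from gfcdmap.preprocess import BoldSeries


@pytest.fixture(scope="session")
def small_cohort():
    """A small imaging cohort reused across tests (3/cell, 40 frames, 10³)."""
    cohort = synth.CohortSpec(n_per_cell=3, n_volumes=40, grid_shape=(10, 10, 10))
    effects = synth.default_effect_spec(grid_shape=(10, 10, 10))
    table, series_list, motion_list = synth.generate_cohort(cohort, effects, seed=11)
    return cohort, effects, table, series_list, motion_list


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_series(data, tr=3.0):
    """Wrap a 4D array as a BoldSeries with a 3 mm diagonal affine."""
    return BoldSeries(np.asarray(data, dtype=float), np.diag([3.0, 3.0, 3.0, 1.0]), tr)
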