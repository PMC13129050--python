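import numpy as np
import pytest

from frugicast.grids import BinaryRangeMap, GridSpec


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def grid():
    return GridSpec(n_rows=4, n_cols=4)


def random_range_map(rng, grid, species_id="sp", scenario="current", p=0.5):
    return BinaryRangeMap(
        (rng.random(grid.shape) < p).astype(int), species_id, scenario, grid
    )
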