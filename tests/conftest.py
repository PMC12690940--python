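import numpy as np
import pytest

from fcdq import synthio as sy
from fcdq import topography as tp


@pytest.fixture(scope="session")
def refmap():
    return sy.make_reference_map()


@pytest.fixture(scope="session")
def map_grid(refmap):
    return tp.MapGrid.for_map(refmap)


@pytest.fixture(scope="session")
def small_cohort(refmap):
    """A reduced cohort (4 seizing / 4 non-seizing) with rasterized masks."""
    params = sy.CohortSimParams(n_seizing=4, n_nonseizing=4, seed=11)
    return sy.simulate_lesion_cohort(params, refmap=refmap)


@pytest.fixture(scope="session")
def default_stack():
    """One simulated Z-stack with intensity frames plus its truth table."""
    return sy.simulate_cell_stack(sy.CellFieldSimParams(seed=21))
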