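import numpy as np
import pandas as pd
import pytest

from stemcover import EffortConfig, make_world, simulate_effort, simulate_species
from stemcover.world import CLIMATE_COVARIATES, HABITAT_CLASSES, WorldGrid


@pytest.fixture(scope="session")
def small_world():
    return make_world(16, 16, 10.0, seed=2)


@pytest.fixture(scope="session")
def world40():
    return make_world(40, 40, 10.0, seed=7)


@pytest.fixture(scope="session")
def small_survey(small_world):
    """One migrating species plus a modest year of effort on the small grid."""
    occ = simulate_species(small_world, seed=1)
    lists = simulate_effort(
        small_world, [occ], EffortConfig(events_per_cell_day=0.06), seed=5
    )
    return occ, lists


def make_uniform_world(n_x: int, n_y: int, **overrides) -> WorldGrid:
    """Hand-built grid with identical covariates everywhere (degenerate cases)."""
    n = n_x * n_y
    cell_id = np.arange(n)
    cells = pd.DataFrame(
        {
            "cell_id": cell_id,
            "x_km": (cell_id % n_x + 0.5) * 10.0,
            "y_km": (cell_id // n_x + 0.5) * 10.0,
        }
    )
    for h in HABITAT_CLASSES:
        cells[h] = overrides.get(h, 0.1)
    cells["elevation"] = overrides.get("elevation", 100.0)
    for c in CLIMATE_COVARIATES:
        cells[c] = overrides.get(c, 10.0)
    return WorldGrid(cells=cells, n_x=n_x, n_y=n_y, cell_size_km=10.0)
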