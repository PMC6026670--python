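import numpy as np
import pytest

from wetareas import hydrology as hy
from wetareas import synthetic as syn
from wetareas.raster import DEMGrid


def random_dem(seed: int, n_rows: int = 30, n_cols: int = 30,
               cell_size: float = 1.0, relief: float = 3.0,
               tilt: float = 0.05) -> DEMGrid:
    """Random rough terrain on a tilt (so it drains after filling)."""
    rng = np.random.default_rng(seed)
    cols = np.arange(n_cols)
    z = 100.0 - tilt * cols[None, :] + rng.normal(0, relief, (n_rows, n_cols))
    return DEMGrid(z, cell_size)


@pytest.fixture(scope="session")
def landscape():
    """One shared synthetic landscape with its 4-ha DTW raster and plots."""
    dem = syn.generate_dem(syn.LandscapeParams(seed=0))
    suite = hy.dtw_suite(dem, [4.0])
    grid = suite.dtw_by_lambda[4.0]
    type_map = syn.assign_forest_types(grid)
    plots = syn.place_plots(type_map, grid, seed=1)
    return {"dem": dem, "dtw": grid, "type_map": type_map, "plots": plots}


@pytest.fixture(scope="session")
def simulated_community(landscape):
    sim = syn.simulate_community(landscape["plots"],
                                 cparams=syn.CommunityParams(seed=7))
    return sim
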