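import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import cwrplan as cp


@pytest.fixture(scope="session")
def small_world():
    """Fast synthetic world shared by unit tests (not acceptance scale)."""
    cfg = cp.LandscapeConfig(
        grid=cp.GridSpec(40, 40, 5.0), seed=7, n_future_realizations=3
    )
    return cp.generate_world(cfg, n_species=6, n_occurrences=120)


@pytest.fixture
def grid10():
    return cp.GridSpec(10, 10, 5.0)


@pytest.fixture
def flat_env():
    """Single-layer-per-set stack with constant-gradient climatic layer."""
    grid = cp.GridSpec(20, 20, 5.0)
    xs, ys = grid.cell_centers()
    layers = {
        "edap_01": np.zeros(grid.shape),
        "geop_01": np.zeros(grid.shape),
        "clim_01": (ys - ys.mean()) / ys.std(),
    }
    sets = {"edap_01": "edaphic", "geop_01": "geophysical", "clim_01": "climatic"}
    return cp.EnvStack(grid=grid, layers=layers, sets=sets)
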