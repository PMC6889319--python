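import numpy as np
import pytest

from acidmac.config import RunConfig
from acidmac.grid import TissueGrid, place_vessels
from acidmac.macrophage import MacrophageParams
from acidmac.tumour import MetabolismParams


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def params():
    return MetabolismParams()


@pytest.fixture
def mac_params():
    return MacrophageParams()


@pytest.fixture
def small_grid():
    """10x10 grid with 5 vessels (seeded), otherwise empty."""
    grid = TissueGrid(width=10, height=10)
    place_vessels(grid, density=0.05, rng_seed=7)
    return grid


@pytest.fixture
def tiny_config():
    """A small, fast configuration used for whole-simulation tests."""
    return RunConfig({"grid": {"width": 24, "height": 24}})
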