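import numpy as np
import pytest

from marshsim.landscape import ClimateGridSpec, build_landscape
from marshsim.synthetic_data import (
    LandscapeSpec,
    gen_climate,
    gen_landscape,
    scenario_spec,
)


@pytest.fixture
def single_climate_landscape():
    """48x48 habitat lattice, all grassland, under one climate cell."""
    grid = np.ones((48, 48), dtype=bool)
    spec = ClimateGridSpec(nx=1, ny=1)
    return build_landscape(grid, spec)


@pytest.fixture
def quad_climate_landscape():
    """96x96 all-grassland lattice under a 2x2 climate lattice."""
    grid = np.ones((96, 96), dtype=bool)
    spec = ClimateGridSpec(nx=2, ny=2)
    return build_landscape(grid, spec)


@pytest.fixture
def small_random_landscape():
    """20x20 lattice with ~50% grassland cover under one climate cell."""
    habitat = gen_landscape(LandscapeSpec(nx=20, ny=20, cover=0.5, seed=42))
    return build_landscape(habitat, ClimateGridSpec(nx=1, ny=1))


@pytest.fixture
def benign_series():
    """Five years of moderate-scenario climate for one climate cell."""
    return gen_climate(
        scenario_spec("MOD"), ClimateGridSpec(nx=1, ny=1), np.arange(2020, 2025),
        seed=3,
    )
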