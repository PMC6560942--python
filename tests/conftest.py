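import numpy as np
import pytest

from nichetrunc.grids import GridGeometry, GridStack
from nichetrunc.occurrences import extract_covariates
from nichetrunc.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced synthetic scenario used by most unit tests."""
    return SimulationConfig(seed=11, n_rows=40, n_cols=40)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """(stack, truth, occurrences-with-covariates) on the reduced scenario."""
    stack, truth, occ = simulate_dataset(small_cfg)
    return stack, truth, extract_covariates(occ, stack)


@pytest.fixture
def tiny_geometry():
    return GridGeometry(n_rows=6, n_cols=6, cell_size=5.0)


@pytest.fixture
def tiny_stack(tiny_geometry):
    rng = np.random.default_rng(42)
    stack = GridStack(tiny_geometry)
    stack.add("A", rng.normal(size=tiny_geometry.shape))
    stack.add("B", rng.normal(size=tiny_geometry.shape))
    return stack
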