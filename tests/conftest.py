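import numpy as np
import pytest

from enzopt.design_space import DesignSpace, ParameterSpec, grid_space
from enzopt.landscapes import make_synthetic_landscape


@pytest.fixture(scope="session")
def coarse_space() -> DesignSpace:
    """Coarse 9x9x9x7x11 grid over the five-parameter box (56,133 points),
    small enough for exhaustive scans."""
    return DesignSpace(
        [
            ParameterSpec("pH", 2.4, 8.0, 0.7),
            ParameterSpec("temperature", 20.0, 60.0, 5.0),
            ParameterSpec("salt", 0.0, 500.0, 62.5),
            ParameterSpec("solvent", 0.0, 30.0, 5.0),
            ParameterSpec("cosubstrate", 0.0, 10.0, 1.0),
        ]
    )


@pytest.fixture(scope="session")
def full_grid_space() -> DesignSpace:
    return grid_space()


@pytest.fixture(scope="session")
def synthetic_coarse(coarse_space):
    """Default synthetic landscape restricted to the coarse grid."""
    return make_synthetic_landscape(space=coarse_space)


@pytest.fixture(scope="session")
def coarse_grid_optimum(synthetic_coarse, coarse_space):
    """Exhaustive-scan argmax of the synthetic landscape on the coarse grid."""
    from enzopt.design_space import enumerate_grid

    best_v, best_p = -np.inf, None
    for p in enumerate_grid(coarse_space):
        v = synthetic_coarse.evaluate(p)
        if v > best_v:
            best_v, best_p = v, p
    return best_p, best_v


@pytest.fixture()
def space1d() -> DesignSpace:
    return DesignSpace([ParameterSpec("x", 0.0, 10.0)])


@pytest.fixture()
def space1d_grid() -> DesignSpace:
    return DesignSpace([ParameterSpec("x", 0.0, 1.0, 0.25)])
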