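import numpy as np
import pytest

from corrloss import (
    CauchyParams,
    CurveGrid,
    ErrorModel,
    apply_error,
    default_grid,
    generate_series,
)

REFERENCE_T = (1.0, 2.0, 3.0, 4.0, 5.0)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def small_grid():
    # coarse grid for property/oracle tests that scale with n^2
    return CurveGrid(np.linspace(900.0, 1100.0, 41))


@pytest.fixture(scope="session")
def shift_params():
    # reference experiment: peak shift coupled to t, linear amplitude
    return CauchyParams(x0=1000.0, gamma=30.0, a=0.0, b=1.0)


@pytest.fixture(scope="session")
def truth_series(grid, shift_params):
    return generate_series(shift_params, grid, REFERENCE_T)


@pytest.fixture(scope="session")
def corrupted_series(truth_series):
    return apply_error(truth_series, ErrorModel(factor=1.1))


@pytest.fixture
def rng():
    return np.random.default_rng(20230420)
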