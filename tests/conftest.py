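import math

import pytest

from gdqprop.grid import build_grid
from gdqprop.propagator import assemble

#: outer boundary of the worked ion-channel example (10^6-step horizon)
EXAMPLE_R_MAX = 5148.0

#: the accuracy/speed-optimal configuration: N=10 quadrature points,
#: 8-point stencils, 25 linear near + 90 log far grid points
OPTIMAL_PARAMS = (10, 8, 25, 90)


@pytest.fixture(scope="session")
def small_grid():
    """Cheap 25-point grid on [0, 50] for unit tests."""
    return build_grid(50.0, 15, 10, tol=math.inf)


@pytest.fixture(scope="session")
def small_P(small_grid):
    return assemble(small_grid, 6, 5)


@pytest.fixture(scope="session")
def optimal_grid():
    return build_grid(EXAMPLE_R_MAX, 25, 90, tol=math.inf)


@pytest.fixture(scope="session")
def optimal_P(optimal_grid):
    return assemble(optimal_grid, 10, 8)
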