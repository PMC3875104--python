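import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from couplefde import PAPER_SECTION5, SolverConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Positive equilibrium of the built-in parameter set, printed to 5 decimals.
EQUILIBRIUM = np.array([4.38469, 0.0, 4.92833, 0.0])


@pytest.fixture(scope="session")
def paper_params():
    return PAPER_SECTION5


@pytest.fixture(scope="session")
def short_solver():
    return SolverConfig(step=0.05, horizon=5.0)
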