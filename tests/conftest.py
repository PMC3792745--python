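import numpy as np
import pytest

from dtiphysio import make_scheme, simulate_physio
from dtiphysio.scenarios import (
    scenario_gated_linear,
    scenario_identity,
    scenario_linear_recovery,
)


@pytest.fixture(scope="session")
def scheme60():
    """Default two-shell scheme: 60 directions at b=700 + 6 low-b volumes."""
    return make_scheme(seed=0)


@pytest.fixture(scope="session")
def physio_2min():
    """Two minutes of simulated pulse + breathing with true beat times."""
    return simulate_physio(duration_s=120.0, seed=5)


@pytest.fixture(scope="session")
def identity_dataset():
    """Noiseless, unperturbed acquisition (b=0 reference)."""
    return scenario_identity(seed=1)


@pytest.fixture(scope="session")
def recovery_dataset():
    """5% cardiac modulation within the linear model span, noiseless."""
    return scenario_linear_recovery(seed=3)


@pytest.fixture(scope="session")
def gated_dataset():
    """Gated acquisition with residual cardiac-locked linear modulation."""
    return scenario_gated_linear(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
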