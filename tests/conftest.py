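import numpy as np
import pytest

from regulonfit import FixtureSpec, TimeGrid, make_fixture
from regulonfit.fitting import AnnealingConfig, FitSettings


@pytest.fixture(scope="session")
def std_fixture():
    """The standard synthetic dataset: 13 time points, 20 ODE targets,
    5 flat decoys, 5 constant-synthesis decoys, noise-free."""
    return make_fixture(FixtureSpec(seed=0))


@pytest.fixture
def grid13():
    return TimeGrid(np.linspace(0.0, 12.0, 13))


@pytest.fixture
def quick_settings():
    """Reduced annealing budget for unit tests where the full 128-restart
    default would be wasteful."""
    return FitSettings(annealing=AnnealingConfig(restarts=16, iterations=300, seed=0))
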