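import numpy as np
import pytest

from circuitfit.model_feedforward import M1Params, make_hand_grid
from circuitfit.model_ssn import ProbeSpec, SSNFixedConfig, ground_truth_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_grid():
    """8-per-axis hand grid: full geometry at unit-test cost."""
    return make_hand_grid(8)


@pytest.fixture(scope="session")
def m1_params():
    """Parameters that give a mostly-active output at grid_size=8."""
    return M1Params(sigma_l=1.0, delta_sigma=1.0, J=2000.0, phi_l=1.0, delta_phi=2.0)


@pytest.fixture(scope="session")
def ssn_config():
    """Reduced SSN profile (N=50, 60 steps, 5 sizes)."""
    return SSNFixedConfig.reduced()


@pytest.fixture(scope="session")
def ssn_truth():
    return ground_truth_params()


@pytest.fixture(scope="session")
def probes():
    return ProbeSpec((0.0, 1 / 8, 3 / 8))


def central_difference(f, x, i, h):
    xp = np.array(x, dtype=float)
    xm = np.array(x, dtype=float)
    xp[i] += h
    xm[i] -= h
    return (f(xp) - f(xm)) / (2.0 * h)
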