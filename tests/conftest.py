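import numpy as np
import pytest

from nucleokit.distribution import FreeEnergyCurve
from nucleokit.thermo import free_energy

FIXED_A, FIXED_B = 1.07e-3, 4.3e-6   # fixed-cell fit parameters
LIVE_A, LIVE_B = 0.166, 0.011        # live-cell fit parameters


@pytest.fixture(scope="session")
def fixed_params():
    return FIXED_A, FIXED_B


@pytest.fixture(scope="session")
def live_params():
    return LIVE_A, LIVE_B


def model_curve(a, b, n_lo=1.5e4, n_hi=3e6, m=40, offset=0.0):
    """Noiseless free-energy curve on a regular grid."""
    n = np.linspace(n_lo, n_hi, m)
    return FreeEnergyCurve(n=n, dG=free_energy(n, a, b) + offset,
                           bin_width=n[1] - n[0])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
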