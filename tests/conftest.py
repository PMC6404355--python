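import numpy as np
import pytest

from hepazone import diffusion, synthetic


@pytest.fixture(scope="session")
def geom():
    return diffusion.ChannelGeometry()


@pytest.fixture(scope="session")
def bc():
    return diffusion.BoundaryConditions()


@pytest.fixture(scope="session")
def presets():
    return synthetic.load_presets()


@pytest.fixture(scope="session")
def day7_profile(presets):
    """The canonical near-linear day-7 gradient used across modules."""
    return presets.day7_profile()


def theta_closed_form(tau: float, n_terms: int = 60) -> float:
    """Mid-channel tangent of the series solution, without windowing.

    theta(tau) = 1 + 2 sum_{m>=1} (-1)^m exp(-4 m^2 pi^2 tau), the exact
    derivative of the Fourier solution at x = L/2 over the global slope.
    """
    m = np.arange(1, n_terms + 1)
    return float(1.0 + 2.0 * np.sum((-1.0) ** m * np.exp(-4.0 * m**2 * np.pi**2 * tau)))
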