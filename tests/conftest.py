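import numpy as np
import pytest

from pwqus.acoustic import ProbeConfig, ScattererField, simulate_rf
from pwqus.phantom import uniform_phantom


@pytest.fixture(scope="session")
def probe():
    return ProbeConfig()


@pytest.fixture(scope="session")
def single_angle_probe():
    return ProbeConfig(steering_angles_deg=(0.0,))


@pytest.fixture(scope="session")
def single_scatterer_rf(single_angle_probe):
    """One scatterer at 20 mm depth in an attenuation-free 1540 m/s medium."""
    ph = uniform_phantom(ac=0.0, sos=1540.0, grid_shape=(128, 128))
    sc = ScattererField(
        positions_mm=np.array([[12.8, 20.0]]),
        amplitudes=np.array([1.0]),
        esd_um=np.array([85.0]),
    )
    return simulate_rf(ph, single_angle_probe, rng_seed=1, scatterers=sc)


@pytest.fixture(scope="session")
def speckle_rf(probe):
    """Fully developed speckle from a uniform phantom (25.6 mm ROI)."""
    ph = uniform_phantom(grid_shape=(128, 128))
    return ph, simulate_rf(ph, probe, rng_seed=2)
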