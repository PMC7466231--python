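import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hsicolor as h

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def grid():
    return h.default_grid()


@pytest.fixture(scope="session")
def small_grid():
    """10-band grid for toy spectra."""
    return h.make_wavelength_grid(400.0, 445.0, 5.0)


@pytest.fixture(scope="session")
def endmembers(grid):
    return h.make_endmembers(grid, 3, seed=1)


@pytest.fixture(scope="session")
def noiseless_scene():
    return h.simulate_scene(height=40, width=40, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_cube(noiseless_scene):
    return h.correct_reflectance(
        noiseless_scene.raw, noiseless_scene.white, noiseless_scene.dark
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
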