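import numpy as np
import pytest

from thetaprime.synthetic import SceneSpec, generate_scene, recompute_theta_prime


@pytest.fixture(scope="session")
def small_scene():
    """Coarse 3-year scene: quick to generate, full planted structure."""
    spec = SceneSpec(lat_step=4.0, lon_step=9.0, n_years=3.0, seed=7)
    return generate_scene(spec)


@pytest.fixture(scope="session")
def small_theta(small_scene):
    return recompute_theta_prime(small_scene)


@pytest.fixture(scope="session")
def noiseless_scene():
    """Scene with observation noise and fast stress fluctuations switched off."""
    spec = SceneSpec(lat_step=8.0, lon_step=18.0, n_years=2.0, seed=3,
                     noise_cv=0.0, stress_cv=0.0)
    return generate_scene(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
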