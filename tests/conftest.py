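import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctsa import compact_phantom, default_phantom, render

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def compact_spec():
    """Reduced study phantom, 10 HU noise."""
    return compact_phantom()


@pytest.fixture(scope="session")
def quiet_spec():
    """Reduced phantom, noiseless, at full rendering fidelity
    (deterministic geometry checks)."""
    return compact_phantom(noise_sd=0.0, supersampling=5)


@pytest.fixture(scope="session")
def quiet_volume(quiet_spec):
    """One noiseless rendering of the reduced phantom at zero displacement."""
    return render(quiet_spec, noise_seed=[0, 0])


@pytest.fixture(scope="session")
def default_spec():
    return default_phantom()


@pytest.fixture(scope="session")
def default_volume(default_spec):
    """Full-size phantom rendering (18 beads, streak artefact, 10 HU noise)."""
    return render(default_spec, noise_seed=[0, 0])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
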