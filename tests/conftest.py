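import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_cylinder():
    """A noise-free, blur-free, straight circular two-scan phantom with no
    events; binarising either volume at the grey midpoint gives the exact
    truth mask."""
    from cortmorph.phantom import PhantomSpec, generate_phantom

    spec = PhantomSpec(bow_amplitude_um=0.0, ellipticity=0.0,
                       noise_sd=0.0, blur_sigma_um=0.0, seed=11)
    volumes, truth = generate_phantom(spec)
    return spec, volumes, truth


@pytest.fixture(scope="session")
def default_phantom():
    """A two-scan phantom under the standard study corruptions (bow,
    ellipticity, vessels, spicules, blur, noise)."""
    from cortmorph.phantom import PhantomSpec, RemodelingEvent, generate_phantom

    spec = PhantomSpec(vessel_count=2, spicule_count=2, seed=5)
    spec.event_list = [
        RemodelingEvent("periosteal", "formation", 0, 40.0, 300.0, 21.0,
                        -60.0, 330.0),
        RemodelingEvent("endocortical", "resorption", 0, 30.0, 250.0, 21.0,
                        120.0, 330.0),
    ]
    volumes, truth = generate_phantom(spec)
    return spec, volumes, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
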