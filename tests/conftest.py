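import numpy as np
import pytest
from hypothesis import settings

import raddwi as rd

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_maps():
    """Default abdominal phantom rasterized at the radial matrix size."""
    return rd.rasterize(rd.default_phantom(), 64)


@pytest.fixture(scope="session")
def small_spec():
    """A two-compartment phantom small enough for brute-force oracles."""
    return rd.PhantomSpec(fov=32.0, compartments=[
        rd.Compartment("disk", (0.0, 0.0), (6.0, 6.0), s0=1.0,
                       d_true=1.5e-3, priority=1),
        rd.Compartment("blob", (5.0, -4.0), (3.0, 2.0), s0=0.6,
                       d_true=0.8e-3, priority=2),
    ])


@pytest.fixture(scope="session")
def small_maps(small_spec):
    return rd.rasterize(small_spec, 32)


@pytest.fixture(scope="session")
def still_model():
    return rd.RespirationModel(displacement_amp=0.0)


@pytest.fixture(scope="session")
def gated_radial_noiseless(default_maps, still_model):
    """One noiseless gated radial acquisition of the default phantom."""
    ks = rd.simulate_radial_kspace(default_maps, rd.radial_params(),
                                   still_model, seed=0)
    return ks
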