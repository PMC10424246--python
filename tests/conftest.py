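import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epidrop.printability import FluidJetSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def water_spec() -> FluidJetSpec:
    """Water-like culture medium jetted through a 250 µm nozzle at 2 m/s."""
    return FluidJetSpec(
        viscosity=1.0e-3,
        surface_tension=0.0728,
        density=998.0,
        orifice_diameter=250e-6,
        droplet_velocity=2.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
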