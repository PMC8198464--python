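import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "workbench",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.filter_too_much],
)
settings.load_profile("workbench")


@pytest.fixture
def dppc_isotherm():
    """Noise-free default DPPC isotherm (400 points)."""
    from langmuir_workbench import generate_isotherm, presets

    return generate_isotherm(presets.DPPC_ISOTHERM, noise_sd=0.0)


@pytest.fixture
def linear_isotherm():
    """Strictly linear pi(A): no plateau, no transition."""
    from langmuir_workbench import Isotherm

    a = np.linspace(1.0, 0.5, 100)
    return Isotherm(area=a, pressure=10.0 * (1.0 - a), label="linear")
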