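import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def water_grid():
    from dktime.synthdata import water_protocol

    p = water_protocol()
    return np.array(p.diffusion_times), np.array(p.b_values)


@pytest.fixture(scope="session")
def metabolite_grid():
    from dktime.synthdata import metabolite_protocol

    p = metabolite_protocol()
    return np.array(p.diffusion_times), np.array(p.b_values)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240405)
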