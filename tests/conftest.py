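import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def short_assay():
    """48 h noiseless assay: covers the full growth phase of both species
    at low K_s and keeps simulation cheap."""
    from serialpulse.growth_curves import AssayConfig

    return AssayConfig(duration_h=48.0, od_noise_sd=0.0)


@pytest.fixture(scope="session")
def week_assay_noiseless():
    from serialpulse.growth_curves import AssayConfig

    return AssayConfig(duration_h=168.0, od_noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
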