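import logging

import pytest
from hypothesis import HealthCheck, settings

import phenflux as pf

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# negative-flux clipping warnings are expected in noisy scenarios
logging.getLogger("phenflux").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def noisefree_config():
    """Default study scenario with measurement noise switched off."""
    return pf.default_scenario(
        seed=11,
        noise_cv_enrichment=0.0,
        noise_cv_concentration=0.0,
        noise_cv_flow=0.0,
    )


@pytest.fixture(scope="session")
def noisefree_dataset(noisefree_config):
    return pf.simulate_subject(noisefree_config, 0, group="healthy_weight")


@pytest.fixture(scope="session")
def subject():
    return pf.SubjectProfile("s01", "healthy_weight", 76.0, 50.0)
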