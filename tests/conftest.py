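import pytest

from maizecanopy import (
    SynthConfig,
    default_params,
    generate_base_profile,
    generate_observations,
)


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def base_profile():
    return generate_base_profile()


@pytest.fixture(scope="session")
def noisefree_observations(base_profile, params):
    """Observation table at the five trial densities with zero noise."""
    config = SynthConfig(noise_sd_percent=0.0, seed=7)
    return generate_observations(base_profile, params, config)
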