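import pytest

from palmtrace.signatures import reference_diets
from palmtrace.simulate import GeneratorConfig, generate


@pytest.fixture(scope="session")
def diets():
    return reference_diets()


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic study bundle, shared across tests."""
    return generate(GeneratorConfig())


@pytest.fixture(scope="session")
def noiseless_config():
    """Generator config with every noise source and the drift zeroed."""
    return GeneratorConfig(
        biological_sd=0.0,
        measurement_sd=0.0,
        noise_sd_crm=0.0,
        drift_slope=1.0,
        drift_intercept=0.0,
    )
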