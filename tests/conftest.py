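import warnings

import pytest
from hypothesis import HealthCheck, settings

from coexffl.synthetic import (
    SimulationConfig,
    simulate_paired_expression,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_fixture(default_config):
    """One draw of the default paired-expression fixture (shared, read-only)."""
    return simulate_paired_expression(default_config)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory, default_config):
    """Full file-based fixture bundle written once per session."""
    from coexffl.synthetic import write_fixture_bundle

    out = tmp_path_factory.mktemp("bundle")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        truth = write_fixture_bundle(default_config, out)
    return out, truth
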