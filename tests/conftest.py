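import logging

import pytest
from hypothesis import HealthCheck, settings

from sclc_cea.config import RunConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("sclc_cea").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def china_config() -> RunConfig:
    return RunConfig.from_name("china")


@pytest.fixture(scope="session")
def us_config() -> RunConfig:
    return RunConfig.from_name("us")


@pytest.fixture(scope="session")
def china_result(china_config):
    from sclc_cea.pipeline import run_base_case

    return run_base_case(china_config)


@pytest.fixture(scope="session")
def us_result(us_config):
    from sclc_cea.pipeline import run_base_case

    return run_base_case(us_config)
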