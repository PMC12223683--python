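import logging

import pytest
from hypothesis import HealthCheck, settings

from lasafe.config import load_catalogue
from lasafe.fixtures import load_fixtures

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# The packaged-catalogue fallback warning is intentional noise in tests.
logging.getLogger("lasafe.config").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def catalogue():
    return load_catalogue()


@pytest.fixture(scope="session")
def study():
    return load_fixtures()
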