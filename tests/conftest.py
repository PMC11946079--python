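import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fertigation_mcda import (
    build_l9_design,
    default_config,
    generate_trial,
    packaged_treatment_table,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def design():
    return build_l9_design()


@pytest.fixture(scope="session")
def treatments():
    return packaged_treatment_table()


@pytest.fixture(scope="session")
def treatment_by_id(treatments):
    return {t.id: t for t in treatments}


@pytest.fixture(scope="session")
def default_trial():
    return generate_trial(default_config(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
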