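import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20221115)


@pytest.fixture(scope="session")
def summary_table_2022():
    from aquarisk.reference import load_summary_table

    return load_summary_table()


@pytest.fixture(scope="session")
def no3_spec():
    """Moment-matched nitrate concentration spec (mean 112, SD 74 mg/L)."""
    from aquarisk.distributions import lognormal_from_mean_sd

    return lognormal_from_mean_sd(112.0, 74.0)
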