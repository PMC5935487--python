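import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

# the pipeline deliberately logs per-trace warnings on degenerate fits;
# keep test output readable
logging.getLogger("obda.imaging").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_timing():
    from obda.imaging import TrialTiming
    return TrialTiming()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
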