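import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def example_counts():
    """A 2x2 case/control table with margins (55, 45) and n = 100."""
    return [[25, 30], [20, 25]]


@pytest.fixture
def example_table(example_counts):
    from dpchisq import build_table

    return build_table(example_counts)
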