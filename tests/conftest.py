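import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from schlogl.params import standard_parameters  # noqa: E402


@pytest.fixture(scope="session")
def std():
    """Standard parameter set at the reference control value B = 3.7."""
    return standard_parameters(3.7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
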