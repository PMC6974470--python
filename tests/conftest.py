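import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def flat_envelope():
    """10 s flat envelope at 0.01, 1 kHz."""
    from tokeda.conditioning import Envelope

    return Envelope(np.full(10_000, 0.01), 1000.0)
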