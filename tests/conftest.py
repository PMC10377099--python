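import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from fusionet.preprocessing import to_luminance
from fusionet.synthetic import PhantomSpec, make_phantom_pair


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom64():
    """One aligned 64x64 phantom pair (structural, functional RGB, truth)."""
    return make_phantom_pair(PhantomSpec(size=64, seed=3))


@pytest.fixture(scope="session")
def phantom64_gray(phantom64):
    """Grayscale working pair: structural slice + functional luminance."""
    structural, functional, _ = phantom64
    return structural, to_luminance(functional)
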