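import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_stack_kwargs():
    """Small confocal geometry shared by puncta/pipeline tests."""
    return dict(n_rod=8, n_cone=2, roi_um=(40.0, 7.5))
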