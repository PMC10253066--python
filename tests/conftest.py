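import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from nsepscreen.synth import GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """A small all-null screen configuration for fast structural tests."""
    return GeneratorConfig(
        n_variants=6,
        plate_size=6,
        n_scr_per_plate=2,
        n_experiments=3,
        cells_per_sample=300,
        seed=42,
    )
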