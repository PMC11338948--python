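import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cxrtubes.geometry import ImageMeta
from cxrtubes.rules import RuleConfig

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def meta():
    return ImageMeta(width=640, height=640, spacing_row=0.5,
                     spacing_col=0.5, image_id="fixture")


@pytest.fixture
def unit_meta():
    """1 mm/pixel so pixel and mm values coincide."""
    return ImageMeta(width=200, height=200, spacing_row=1.0,
                     spacing_col=1.0, image_id="unit")


@pytest.fixture
def cfg():
    return RuleConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
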