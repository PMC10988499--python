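import numpy as np
import pytest

from capdomain import CapillaryMap, generate_cross_section
from capdomain.synth import CORE_PRESET


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_map(rng):
    """50 uniform-random capillaries in the default-size square frame."""
    side = 380.0
    pts = rng.uniform(5.0, side - 5.0, size=(50, 2))
    return CapillaryMap(frame_width=side, frame_height=side, capillaries=pts)


@pytest.fixture(scope="session")
def core_section():
    """One synthetic oxidative-core cross-section (seeded)."""
    return generate_cross_section(CORE_PRESET, seed=7)
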