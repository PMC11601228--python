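import numpy as np
import pytest

from phagoscreen import build_synthetic_library, example_validation_library
from phagoscreen.screen_simulator import ScreenConfig


@pytest.fixture(scope="session")
def validation_library():
    """The ten-guide knockdown-validation library (2 NTCs + 4 genes x 2)."""
    return example_validation_library()


@pytest.fixture(scope="session")
def small_library():
    """A quick 6-gene synthetic library for pipeline tests."""
    return build_synthetic_library(6, 2, 8, 20, seed=11)


@pytest.fixture(scope="session")
def screen_library():
    """Full-scale screen design: 102 genes x 2 guides + 28 NTCs."""
    return build_synthetic_library(102, 2, 28, 20, seed=1)


@pytest.fixture
def fast_config(small_library):
    """A small, fast screen configuration with no true effects."""
    return ScreenConfig(small_library, cells_per_guide=100,
                        reads_per_bin=50_000, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
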