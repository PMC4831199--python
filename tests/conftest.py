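import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_volume(rng):
    """5x5x5 random intensities in [0, 200]."""
    return rng.uniform(0.0, 200.0, size=(5, 5, 5))


@pytest.fixture
def medium_volume(rng):
    """7x7x7 random intensities in [0, 200]."""
    return rng.uniform(0.0, 200.0, size=(7, 7, 7))
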