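import numpy as np
import pytest

from rnapalloc import default_system
from rnapalloc.synthetic import GeneratorConfig


@pytest.fixture
def system():
    """Four-fragment allocator with tight (SynZIP) binding."""
    return default_system()


@pytest.fixture
def noiseless_config():
    """Generator config with noise and background switched off."""
    return GeneratorConfig(noise_cv=0.0, white_cell_mean=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
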