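import numpy as np
import pytest
from hypothesis import settings

from hetquant import synthdata as sd

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_spread_spec():
    """A small, fast spread image: 2 pairs on a 128x128 grid."""
    return sd.SpreadImageSpec(shape=(128, 128), n_pairs=2, min_pair_spacing=50.0,
                              noise_sd=0.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
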