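import numpy as np
import pytest
from hypothesis import settings

from tagdge.synthetic_data import random_reference

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_reference():
    """Three random unigenes, ~1 kb each."""
    return random_reference(3, length_range=(800, 1200), seed=7)
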