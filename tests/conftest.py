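import numpy as np
import pytest

from emotrend.config import SimConfig
from emotrend.emotion import load_lexicon
from emotrend.synthetic import generate_corpus


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_users=80, seed=3)


@pytest.fixture(scope="session")
def small_corpus(small_config):
    """A small generated corpus with texts, plus its ground-truth ledger."""
    return generate_corpus(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
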