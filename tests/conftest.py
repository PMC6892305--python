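import numpy as np
import pytest

from medrelex.encoder import EncoderConfig, EncoderParams
from medrelex.synthetic import fixture_1601297
from medrelex.wordpiece import SPECIALS, Vocabulary


@pytest.fixture(scope="session")
def cocaine_doc():
    """The worked-example BC5CDR record (cocaine ECG study)."""
    return fixture_1601297()


@pytest.fixture(scope="session")
def fig5_vocab():
    """Vocabulary containing exactly the word pieces of the illustration
    sentence 'suxamethonium masseter spasm a dose-response study'."""
    tokens = list(SPECIALS) + [
        "su", "##xa", "##met", "##hon", "##ium",
        "mass", "##eter", "spasm", "a", "dose", "-", "response", "study", ".",
        "cocaine", "myocardial", "infarction",
    ]
    return Vocabulary(tokens)


@pytest.fixture(scope="session")
def tiny_config():
    return EncoderConfig(n_layers=2, hidden=8, n_heads=2, vocab_size=30,
                         max_positions=16, dropout=0.0)


@pytest.fixture(scope="session")
def tiny_params(tiny_config):
    return EncoderParams.init(tiny_config, seed=0)
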