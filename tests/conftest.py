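import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import xraycap as xc


@pytest.fixture(scope="session")
def phantom_spec():
    return xc.PhantomSpec(seed=42)


@pytest.fixture(scope="session")
def phantom_batch(phantom_spec):
    """A small fixed batch of phantoms shared across tests."""
    return [xc.generate_phantom(phantom_spec, i) for i in range(24)]


@pytest.fixture(scope="session")
def phantom_corpus(phantom_batch):
    """Token lists, vocabulary and encoded sequences for the batch."""
    token_lists = [xc.normalize_text(s.report) for s in phantom_batch]
    vocab = xc.build_vocab(token_lists)
    sequences = [xc.encode_caption(t, vocab, 40) for t in token_lists]
    return token_lists, vocab, sequences


@pytest.fixture(scope="session")
def tiny_sat(phantom_corpus):
    """An untrained, seeded captioner with small dimensions."""
    _, vocab, _ = phantom_corpus
    cfg = xc.SatConfig(vocab_size=len(vocab), embed_dim=16, hidden_dim=24,
                       attn_dim=24, dropout=0.0, max_len=12, seed=3)
    return xc.SatModel(cfg, rng=np.random.default_rng(3))


@pytest.fixture(scope="session")
def phantom_sentences(phantom_batch):
    """Plain report sentences used as a text corpus."""
    return [" ".join(xc.normalize_text(s.report)) for s in phantom_batch]
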