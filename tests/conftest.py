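from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from protlm import io_seq, lm, synthetic, tokenizer

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def two_state_setup():
    """A tiny transformer trained on the symmetric stay-0.9 two-state chain.

    Entropy rate −(0.9 ln 0.9 + 0.1 ln 0.1) ≈ 0.3251 nats/symbol; the desk
    budget (300 sequences, 300 Adam steps) reliably converges well inside
    the 0.05-nat recovery band.
    """
    grammar = synthetic.two_state_grammar(
        0.9,
        length_spec=io_seq.LengthSpec(min_len=30, max_len=200, mean=120.0, sd=40.0),
        seed=3,
    )
    corpus = synthetic.sample_corpus(grammar, 300)
    tkz = tokenizer.bpe_train(corpus, vocab_size=4)  # character-level
    split = io_seq.split_dataset(corpus, 0.1, seed=5)
    cfg = lm.LMConfig(
        vocab_size=tkz.vocab_size,
        n_layers=2,
        d_model=32,
        n_heads=2,
        context_length=64,
        learning_rate=3e-3,
        batch_tokens=1024,
        seed=11,
    )
    model = lm.LanguageModel(cfg)
    trace = lm.train(model, split, tkz, steps=300)
    return model, grammar, tkz, trace


@pytest.fixture(scope="session")
def skewed_markov_setup():
    """A model trained on a strongly non-uniform three-symbol chain
    (stationary ≈ [0.74, 0.18, 0.08]) for calibration experiments."""
    grammar = synthetic.MarkovGrammar(
        alphabet=("A", "B", "C"),
        initial=np.array([0.7, 0.2, 0.1]),
        transitions=np.array(
            [[0.8, 0.15, 0.05], [0.6, 0.3, 0.1], [0.5, 0.2, 0.3]]
        ),
        length_spec=io_seq.LengthSpec(min_len=20, max_len=120, mean=60.0, sd=20.0),
        seed=7,
    )
    corpus = synthetic.sample_corpus(grammar, 300)
    tkz = tokenizer.bpe_train(corpus, vocab_size=5)
    split = io_seq.split_dataset(corpus, 0.1, seed=5)
    cfg = lm.LMConfig(
        vocab_size=tkz.vocab_size,
        n_layers=2,
        d_model=32,
        n_heads=2,
        context_length=64,
        learning_rate=3e-3,
        batch_tokens=1024,
        seed=11,
    )
    model = lm.LanguageModel(cfg)
    lm.train(model, split, tkz, steps=250)
    return model, grammar, tkz
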