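import numpy as np
import pytest

from hbsl.learner import DirichletMarkovModel, learn_sequence
from hbsl.symbolic import make_fixture_melody_with_motif, tokenize


@pytest.fixture(scope="session")
def fixture_melody():
    """Default 40-note planted-motif melody plus the motif's pitches."""
    return make_fixture_melody_with_motif()


@pytest.fixture(scope="session")
def fixture_tokens(fixture_melody):
    seq, _ = fixture_melody
    return tokenize(seq, "pitch")


@pytest.fixture(scope="session")
def dense_motif_tokens():
    """Denser fixture (motif 20x in 100 notes) with the motif's token ids."""
    seq, motif = make_fixture_melody_with_motif(
        n_notes=100, alphabet_size=8, motif_length=4, motif_repeats=20, seed=11
    )
    tok = tokenize(seq, "pitch")
    pitch_to_token = {p: i for i, p in enumerate(tok.alphabet)}
    return tok, tuple(pitch_to_token[p] for p in motif)


def train_model(tokens, factor=1.0, trials=1, **kwargs):
    model = DirichletMarkovModel(tokens.K, sensitivity_factor=factor, **kwargs)
    traces = []
    for trial in range(1, trials + 1):
        model, trace = learn_sequence(model, tokens.tokens, trial_index=trial)
        traces.append(trace)
    return model, traces


@pytest.fixture(scope="session")
def trained_models(fixture_tokens):
    """Five-trial models for the three sensitivity regimes."""
    out = {}
    for name, factor in [("hypo", 0.25), ("normal", 1.0), ("hyper", 4.0)]:
        model, traces = train_model(fixture_tokens, factor, trials=5)
        out[name] = (model, traces)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
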