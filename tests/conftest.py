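import numpy as np
import pytest

import lossgate as lg


@pytest.fixture(scope="session")
def small_spec() -> lg.CorpusSpec:
    return lg.CorpusSpec(n_clean_per_class=40, n_test_per_class=15, seed=123)


@pytest.fixture(scope="session")
def small_corpus(small_spec) -> lg.Corpus:
    return lg.generate_corpus(small_spec)


@pytest.fixture(scope="session")
def trained_small(small_corpus):
    """A quickly trained joint model + trace on a small clean labeled set."""
    clean = [
        p.id for p in small_corpus.patches if p.split == "pool" and p.noise_type == "none"
    ]
    rng = np.random.default_rng(9)
    ids = sorted(rng.choice(clean, 60, replace=False))
    model = lg.JointModel(seed=42)
    model, trace = lg.train_joint(
        model,
        small_corpus.images(ids),
        small_corpus.labels(ids),
        lg.TrainConfig(epochs=8, seed=42),
    )
    return model, trace, ids
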