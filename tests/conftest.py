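import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from bcpred.sequence_io import ALPHABET, ProteinRecord
from bcpred.simulate import FixtureConfig, generate_corpus


def random_sequence(rng, length):
    return "".join(ALPHABET[i] for i in rng.integers(0, 20, size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture(scope="session")
def small_corpus():
    """Strongly separable two-class corpus for fast end-to-end tests."""
    config = FixtureConfig(
        n_pos=40, n_neg=60, min_length=35, max_length=120, delta=0.3, seed=7
    )
    return generate_corpus(config)


@pytest.fixture(scope="session")
def small_bundle(small_corpus):
    """A trained AC+DC bundle on the small corpus (fast, low-dimensional)."""
    from bcpred.bench import train_model

    pos, neg = small_corpus
    bundle, cv = train_model(
        pos, neg, families=("AC", "DC"), reduction="kbest-chi2", k=50,
        classifier="LR", n_folds=3, seed=7,
    )
    return bundle


@pytest.fixture
def toy_records():
    return [
        ProteinRecord("p1", "ACDEFGHIKLMNPQRSTVWY"),
        ProteinRecord("p2", "AAAAACCCCCDDDDDEEEEE"),
        ProteinRecord("p3", "WYWYWYWYWYWYWYWYWYWY"),
    ]
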