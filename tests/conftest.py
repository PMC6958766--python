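"""Shared fixtures.

The synthetic corpus and the trained classifiers are expensive, so they
are built once per session and shared by every test that needs them.
"""

import numpy as np
import pytest

import premirnet as pm
from premirnet.models import positive_scores


@pytest.fixture(scope="session")
def corpus():
    """The frozen-seed 200+200 synthetic hairpin corpus."""
    return pm.fixture_corpus()


@pytest.fixture(scope="session")
def corpus_splits(corpus):
    """Deterministic 64/16/20 stratified split of the corpus."""
    return pm.split(corpus, pm.SplitSpec(seed=11))


@pytest.fixture(scope="session")
def corpus_encoded(corpus_splits):
    return tuple(pm.encode_table(part) for part in corpus_splits)


@pytest.fixture(scope="session")
def trained_cnn(corpus_encoded):
    """Default CNN trained on the corpus train/val split (shared)."""
    train_e, val_e, _ = corpus_encoded
    clf, history = pm.train(pm.build_cnn(), train_e, val_e, pm.TrainingConfig(seed=11))
    return clf, history


@pytest.fixture(scope="session")
def trained_rnn(corpus_encoded):
    """Default stacked-LSTM classifier trained on the same split (shared)."""
    train_e, val_e, _ = corpus_encoded
    clf, history = pm.train(pm.build_rnn(), train_e, val_e, pm.TrainingConfig(seed=11))
    return clf, history


@pytest.fixture(scope="session")
def cnn_test_scores(trained_cnn, corpus_encoded):
    """(labels, positive-class scores) of the shared CNN on the test split."""
    _, _, (test_mats, test_labels) = corpus_encoded
    clf, _ = trained_cnn
    return np.asarray(test_labels), positive_scores(clf, test_mats)


def small_labeled_table(n_per_class: int = 6, seed: int = 3) -> pm.DatasetTable:
    """A tiny labeled table for cheap unit tests."""
    return pm.generate(
        pm.SyntheticSpec(
            n_pos=n_per_class,
            n_neg=n_per_class,
            length_range=(30, 40),
            stem_length_range=(10, 13),
            seed=seed,
        )
    )


@pytest.fixture()
def tiny_table():
    return small_labeled_table()
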