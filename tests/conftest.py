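import numpy as np
import pytest

from ftdsim.embeddings import EmbeddingTable, HashingSentenceEncoder, make_fixture_table
from ftdsim.lm_backend import (
    FULL_STOP,
    END_OF_TEXT,
    Vocabulary,
    make_clustered_bigram,
    make_topic_window,
)
from ftdsim.preprocessing import DictionaryLemmatizer


@pytest.fixture(scope="session")
def cluster_backend():
    return make_clustered_bigram(4, 8, 0.95, seed=7)


@pytest.fixture(scope="session")
def topic_backend():
    return make_topic_window(12, 5, seed=7)


@pytest.fixture(scope="session")
def cluster_table(cluster_backend):
    return make_fixture_table(
        cluster_backend.vocabulary, 24, cluster_backend.cluster_of, seed=11
    )


@pytest.fixture(scope="session")
def topic_table(topic_backend):
    return make_fixture_table(
        topic_backend.vocabulary, 24, topic_backend.topic_of, seed=11,
        chain_strength=0.8,
    )


@pytest.fixture(scope="session")
def hashing_encoder():
    return HashingSentenceEncoder()


@pytest.fixture
def tiny_vocab():
    return Vocabulary(("aa", "bb", "cc", FULL_STOP, END_OF_TEXT))


@pytest.fixture(scope="session")
def hand_table():
    """Small hand-built table with known geometry."""
    vectors = {
        "king": np.array([1.0, 0.0, 0.0]),
        "queen": np.array([0.9, 0.1, 0.0]),
        "apple": np.array([0.0, 1.0, 0.0]),
        "pear": np.array([0.0, 0.9, 0.1]),
        "anti": np.array([-1.0, 0.0, 0.0]),
        "diag": np.array([1.0, 1.0, 0.0]),
        "up": np.array([0.0, 0.0, 1.0]),
    }
    return EmbeddingTable(name="hand", dimension=3, vectors=vectors)


@pytest.fixture(scope="session")
def simple_lemmatizer():
    return DictionaryLemmatizer()


def random_table(rng: np.random.Generator, n_words: int = 20, dim: int = 8) -> EmbeddingTable:
    """Isotropic random embedding table for oracle tests."""
    vectors = {
        f"word{i}": rng.standard_normal(dim) for i in range(n_words)
    }
    return EmbeddingTable(name="random", dimension=dim, vectors=vectors)
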