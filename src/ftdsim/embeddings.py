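"""Word and sentence vector representations.

Static word embeddings are held in an :class:`EmbeddingTable` loaded from the
standard word2vec text format (one header line ``n_vectors dimension``, then
``word v1 v2 ...`` per line) — the same format published GloVe, word2vec and
fastText exports use. Sentences are encoded either as the mean of their words'
static vectors or by a :class:`SentenceEncoder` (deterministic sentence string
-> fixed-dimension vector).

Two self-contained constructions support hermetic testing and the toy-backend
ground truths:

* :func:`make_fixture_table` — a cluster-structured table where words sharing
  a cluster have systematically higher cosine similarity than words in
  different clusters (cluster centroid plus small isotropic noise);
* :class:`HashingSentenceEncoder` — a deterministic contextual-encoder stand-in
  that projects word and word-pair (co-occurrence window) identities into a
  fixed-dimension space via hashing, so identical sentences always map to the
  same unit vector and word order influences the encoding.

Out-of-vocabulary policy: OOV words are skipped silently but counted, so the
OOV rate per narrative is auditable. No subword composition is attempted even
for fastText-derived tables.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

from .lm_backend import Vocabulary

__all__ = [
    "EmbeddingTable",
    "SentenceEncoder",
    "HashingSentenceEncoder",
    "SentenceTransformerEncoder",
    "encode_sentence_mean",
    "make_fixture_table",
    "read_word2vec_text",
    "write_word2vec_text",
]


@dataclass
class EmbeddingTable:
    """Word -> dense vector map with a fixed dimension.

    All vectors share ``dimension``; all-zero vectors are rejected at
    construction because they have no direction for cosine distance.
    """

    name: str
    dimension: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for word, vec in self.vectors.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.dimension,):
                raise ValueError(f"vector for {word!r} has wrong dimension")
            if not np.any(vec):
                raise ValueError(f"all-zero vector for {word!r}")
            clean[word] = vec
        self.vectors = clean

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def lookup(self, word: str) -> np.ndarray | None:
        """Exact-match lookup; None for out-of-vocabulary words."""
        return self.vectors.get(word)

    def matrix(self, words: Sequence[str]) -> tuple[np.ndarray, list[int]]:
        """Stack vectors for the in-vocabulary subset of ``words``.

        Returns (matrix, kept_indices); OOV words are skipped with their
        positions dropped from ``kept_indices``.
        """
        rows = []
        kept = []
        for i, w in enumerate(words):
            vec = self.vectors.get(w)
            if vec is not None:
                rows.append(vec)
                kept.append(i)
        if not rows:
            return np.empty((0, self.dimension)), []
        return np.vstack(rows), kept

    def oov_rate(self, words: Sequence[str]) -> float:
        if not words:
            return 0.0
        return sum(1 for w in words if w not in self.vectors) / len(words)


def encode_sentence_mean(
    words: Sequence[str], table: EmbeddingTable
) -> np.ndarray | None:
    """Mean of the static vectors of the sentence's in-vocabulary words.

    OOV words are skipped; returns None when no word is found. The result can
    be the zero vector when vectors cancel — callers must treat that as a
    degenerate sentence for cosine purposes.
    """
    mat, kept = table.matrix(words)
    if not kept:
        return None
    return mat.mean(axis=0)


def make_fixture_table(
    vocabulary: Vocabulary | Iterable[str],
    dimension: int,
    cluster_map: Mapping[str, int],
    seed: int,
    *,
    noise_scale: float = 0.15,
    chain_strength: float = 0.0,
    name: str = "fixture",
) -> EmbeddingTable:
    """Reproducible cluster-aligned embedding table.

    Each cluster gets a random unit centroid; each word's vector is its
    cluster centroid plus isotropic Gaussian noise of scale ``noise_scale``.
    Same-cluster words therefore have higher pairwise cosine similarity than
    cross-cluster words. Words of ``vocabulary`` absent from ``cluster_map``
    (e.g. punctuation) receive no vector.

    With ``chain_strength`` alpha in (0, 1) the centroids form a smooth chain
    in cluster-id order (an AR(1) walk on the unit sphere with lag-1 cosine
    similarity about alpha), so semantically "adjacent" clusters are closer
    than distant ones — mirroring how related topics are embedded closer than
    unrelated ones. alpha = 0 (default) keeps centroids independent.
    """
    if dimension < 2:
        raise ValueError("dimension must be >= 2")
    if not (0.0 <= chain_strength < 1.0):
        raise ValueError("chain_strength must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    clusters = sorted(set(cluster_map.values()))
    centroids = {}
    prev = None
    for c in clusters:
        fresh = rng.standard_normal(dimension)
        fresh /= np.linalg.norm(fresh)
        if prev is None or chain_strength == 0.0:
            v = fresh
        else:
            v = chain_strength * prev + np.sqrt(1.0 - chain_strength**2) * fresh
        v = v / np.linalg.norm(v)
        centroids[c] = v
        prev = v
    tokens = list(vocabulary.tokens) if isinstance(vocabulary, Vocabulary) else list(vocabulary)
    vectors = {}
    for word in tokens:
        if word not in cluster_map:
            continue
        vec = centroids[cluster_map[word]] + noise_scale * rng.standard_normal(dimension)
        if not np.any(vec):  # vanishingly unlikely; keep the no-zero invariant
            vec = centroids[cluster_map[word]]
        vectors[word] = vec
    return EmbeddingTable(name=name, dimension=dimension, vectors=vectors)


# ---------------------------------------------------------------------------
# word2vec text format IO
# ---------------------------------------------------------------------------

def read_word2vec_text(path: str | Path, *, name: str | None = None) -> EmbeddingTable:
    """Load a table from word2vec text format (header ``n dim``)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("expected 'n_vectors dimension' header line")
        n, dim = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"malformed vector line for {parts[0]!r}")
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    if len(vectors) != n:
        raise ValueError(f"header promised {n} vectors, found {len(vectors)}")
    return EmbeddingTable(name=name or path.stem, dimension=dim, vectors=vectors)


def write_word2vec_text(table: EmbeddingTable, path: str | Path, *, fmt: str = "%.8g") -> None:
    """Write a table in word2vec text format."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors)} {table.dimension}\n")
        for word, vec in table.vectors.items():
            fh.write(word + " " + " ".join(fmt % x for x in vec) + "\n")


# ---------------------------------------------------------------------------
# sentence encoders
# ---------------------------------------------------------------------------


@runtime_checkable
class SentenceEncoder(Protocol):
    """Deterministic sentence string -> fixed-dimension vector."""

    dimension: int

    def encode(self, sentence: str) -> np.ndarray:
        ...


_ENC_WORD_RE = re.compile(r"[a-z0-9']+")


class HashingSentenceEncoder:
    """Deterministic contextual-encoder stand-in based on feature hashing.

    Each word, and each adjacent word pair (a 2-word co-occurrence window),
    is mapped to a fixed pseudo-random direction derived from a cryptographic
    hash of the string, independent of the process hash seed. The sentence
    vector is the weighted sum of its word and pair directions, normalized to
    unit length. Word order matters through the pair features, identical
    strings always encode identically, and the output dimension is constant —
    the contract a contextualized sentence encoder must satisfy.
    """

    def __init__(self, dimension: int = 64, *, pair_weight: float = 0.5, salt: str = ""):
        if dimension < 2:
            raise ValueError("dimension must be >= 2")
        self.dimension = dimension
        self.pair_weight = pair_weight
        self.salt = salt
        self._cache: dict[str, np.ndarray] = {}

    def _direction(self, key: str) -> np.ndarray:
        vec = self._cache.get(key)
        if vec is None:
            digest = hashlib.blake2b((self.salt + key).encode("utf-8"), digest_size=8).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "big"))
            vec = rng.standard_normal(self.dimension)
            vec /= np.linalg.norm(vec)
            self._cache[key] = vec
        return vec

    def encode(self, sentence: str) -> np.ndarray:
        words = _ENC_WORD_RE.findall(sentence.lower())
        if not words:
            return self._direction("<empty>")
        total = np.zeros(self.dimension)
        for w in words:
            total += self._direction("w:" + w)
        for a, b in zip(words, words[1:]):
            total += self.pair_weight * self._direction(f"p:{a}|{b}")
        norm = np.linalg.norm(total)
        if norm == 0.0:  # cancellation is possible in principle
            return self._direction("<degenerate>")
        return total / norm


class SentenceTransformerEncoder:
    """Adapter to a pretrained contextual sentence encoder.

    Pass any sentence-transformers identifier, e.g. ``all-MiniLM-L12-v2``,
    ``all-mpnet-base-v2`` or ``all-distilroberta-v1``. Requires the optional
    ``encoders`` extra; never used by the test suite.
    """

    def __init__(self, model_id: str = "all-MiniLM-L12-v2", device: str = "cpu"):
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "SentenceTransformerEncoder requires the 'encoders' extra "
                "(pip install ftdsim[encoders])"
            ) from exc
        self.model = SentenceTransformer(model_id, device=device)  # pragma: no cover
        self.dimension = self.model.get_sentence_embedding_dimension()  # pragma: no cover

    def encode(self, sentence: str) -> np.ndarray:  # pragma: no cover - optional
        return np.asarray(self.model.encode([sentence])[0], dtype=float)
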