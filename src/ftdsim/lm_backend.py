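"""Next-token-distribution backends.

Every generator in this package consumes the same contract: a backend maps a
non-empty token context to a normalized probability distribution over a fixed
vocabulary. Two self-contained toy backends provide known ground truth for the
two decoding perturbations studied here:

* :class:`ClusteredBigramModel` — a bigram chain whose vocabulary is organized
  into semantic clusters with "sticky" within-cluster transitions. Raising the
  sampling temperature provably increases the rate of cross-cluster jumps, so
  the model is a ground truth for the word-selection-stochasticity perturbation.
* :class:`TopicWindowModel` — a topic-conditional model that re-infers the
  active topic from only the tokens visible in the supplied context. Shrinking
  the context window makes the topic drift, so the model is a ground truth for
  the bounded-memory-span perturbation.

A thin adapter to a pretrained autoregressive transformer is provided for real
runs; it requires the optional ``transformer`` extra and is never exercised by
the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

__all__ = [
    "END_OF_TEXT",
    "FULL_STOP",
    "Vocabulary",
    "TokenDistribution",
    "LMBackend",
    "ClusteredBigramModel",
    "TopicWindowModel",
    "TransformerBackend",
    "make_clustered_bigram",
    "make_topic_window",
    "next_token_distribution",
]

END_OF_TEXT = "<|endoftext|>"
FULL_STOP = "."

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token inventory with an end-of-text sentinel and a full stop."""

    tokens: tuple[str, ...]
    end_of_text: str = END_OF_TEXT
    full_stop: str = FULL_STOP

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary contains duplicate tokens")
        if len(self.tokens) < 2:
            raise ValueError("vocabulary must contain at least 2 tokens")
        if self.end_of_text not in self.tokens:
            raise ValueError("end-of-text sentinel missing from vocabulary")
        if self.full_stop not in self.tokens:
            raise ValueError("full-stop token missing from vocabulary")
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(self.tokens)})

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index  # type: ignore[attr-defined]

    def index(self, token: str) -> int:
        """Integer id of ``token``; raises KeyError for unknown tokens."""
        return self._index[token]  # type: ignore[attr-defined]

    def get(self, token: str, default: int = -1) -> int:
        return self._index.get(token, default)  # type: ignore[attr-defined]

    @property
    def eot_id(self) -> int:
        return self.index(self.end_of_text)

    @property
    def stop_id(self) -> int:
        return self.index(self.full_stop)

    @property
    def word_ids(self) -> np.ndarray:
        """Ids of ordinary word tokens (everything but sentinel and full stop)."""
        special = {self.eot_id, self.stop_id}
        return np.array([i for i in range(len(self.tokens)) if i not in special])

    def to_ids(self, tokens: Iterable[str]) -> list[int]:
        """Map tokens to ids; unknown tokens become -1 (backend OOV policy applies)."""
        idx = self._index  # type: ignore[attr-defined]
        return [idx.get(t, -1) for t in tokens]


class TokenDistribution:
    """Normalized probability distribution over a vocabulary.

    Stored densely as a probability vector aligned with the vocabulary order;
    :attr:`probabilities` exposes the token -> probability mapping view.
    """

    __slots__ = ("vocabulary", "probs")

    def __init__(self, vocabulary: Vocabulary, probs: np.ndarray, *, validate: bool = True):
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (len(vocabulary),):
            raise ValueError("probability vector length does not match vocabulary size")
        if validate:
            if np.any(probs < -_PROB_TOL):
                raise ValueError("negative probability in token distribution")
            total = probs.sum()
            if abs(total - 1.0) > _PROB_TOL:
                raise ValueError(f"token distribution sums to {total!r}, not 1")
        self.vocabulary = vocabulary
        self.probs = probs

    @classmethod
    def from_mapping(cls, vocabulary: Vocabulary, mapping: Mapping[str, float]) -> "TokenDistribution":
        probs = np.zeros(len(vocabulary))
        for token, p in mapping.items():
            probs[vocabulary.index(token)] = p
        return cls(vocabulary, probs)

    @property
    def probabilities(self) -> dict[str, float]:
        """Token -> probability map over the support (zero entries omitted)."""
        return {
            t: float(p)
            for t, p in zip(self.vocabulary.tokens, self.probs)
            if p > 0.0
        }

    def __getitem__(self, token: str) -> float:
        return float(self.probs[self.vocabulary.index(token)])

    def validate(self) -> None:
        TokenDistribution(self.vocabulary, self.probs, validate=True)


@runtime_checkable
class LMBackend(Protocol):
    """Contract every narrative generator consumes."""

    vocabulary: Vocabulary

    def next_token_distribution(self, context: Sequence[str]) -> TokenDistribution:
        ...

    def _row_ids(self, context_ids: Sequence[int]) -> np.ndarray:
        """Fast path: probability vector for an id-encoded context."""
        ...


def next_token_distribution(backend: LMBackend, context: Sequence[str]) -> TokenDistribution:
    """Query ``backend`` for the distribution of the token following ``context``.

    The context must be non-empty; unknown tokens are handled by the backend's
    out-of-vocabulary policy (toy backends back off to a uniform distribution).
    The result is a deterministic function of (backend, context).
    """
    if len(context) == 0:
        raise ValueError("context must be non-empty")
    return backend.next_token_distribution(context)


def _check_context(context: Sequence[str]) -> None:
    if len(context) == 0:
        raise ValueError("context must be non-empty")


class ClusteredBigramModel:
    """Bigram chain over a cluster-structured vocabulary.

    Word tokens are partitioned into clusters. Conditional on emitting a word
    (rather than the full stop or the end-of-text sentinel), a fixed fraction
    ``within_mass`` of the transition probability stays inside the current
    token's cluster. Because the full stop consumes a fixed per-step
    probability, ``within_mass`` is defined on the word-conditional
    distribution: ``P(next in same cluster | next is a word) = within_mass``.

    The full-stop row is uniform over word tokens, so sentences restart from a
    random cluster.
    """

    def __init__(
        self,
        vocabulary: Vocabulary,
        cluster_of: Mapping[str, int],
        rows: np.ndarray,
        within_mass: float,
        stop_prob: float,
    ):
        self.vocabulary = vocabulary
        self.cluster_of = dict(cluster_of)
        self.rows = np.asarray(rows, dtype=float)
        self.within_mass = float(within_mass)
        self.stop_prob = float(stop_prob)
        v = len(vocabulary)
        if self.rows.shape != (v, v):
            raise ValueError("transition matrix shape does not match vocabulary")
        self._uniform = np.full(v, 1.0 / v)
        self._cluster_id = np.full(v, -1, dtype=int)
        for token, cid in self.cluster_of.items():
            self._cluster_id[vocabulary.index(token)] = cid
        self._validate()

    def _validate(self) -> None:
        sums = self.rows.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _PROB_TOL) or np.any(self.rows < -_PROB_TOL):
            raise ValueError("transition rows are not valid distributions")
        word_mask = self._cluster_id >= 0
        n_clusters = len(set(self.cluster_of.values()))
        expected = self.within_mass if n_clusters > 1 else 1.0
        for i in np.flatnonzero(word_mask):
            row = self.rows[i]
            word_mass = row[word_mask].sum()
            if word_mass <= 0:
                raise ValueError("word row assigns no mass to word successors")
            same = row[word_mask & (self._cluster_id == self._cluster_id[i])].sum()
            if abs(same / word_mass - expected) > 1e-9:
                raise ValueError(
                    "within-cluster conditional mass deviates from within_mass"
                )

    # -- backend contract ---------------------------------------------------
    def next_token_distribution(self, context: Sequence[str]) -> TokenDistribution:
        _check_context(context)
        ids = self.vocabulary.to_ids(context)
        return TokenDistribution(self.vocabulary, self._row_ids(ids))

    def _row_ids(self, context_ids: Sequence[int]) -> np.ndarray:
        prev = context_ids[-1]
        if prev < 0:  # unknown token: uniform back-off
            return self._uniform
        return self.rows[prev]

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "clustered_bigram",
                "tokens": list(self.vocabulary.tokens),
                "end_of_text": self.vocabulary.end_of_text,
                "full_stop": self.vocabulary.full_stop,
                "cluster_of": self.cluster_of,
                "rows": self.rows.tolist(),
                "within_mass": self.within_mass,
                "stop_prob": self.stop_prob,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "ClusteredBigramModel":
        d = json.loads(payload)
        if d.get("kind") != "clustered_bigram":
            raise ValueError("payload does not describe a clustered bigram model")
        vocab = Vocabulary(tuple(d["tokens"]), d["end_of_text"], d["full_stop"])
        return cls(vocab, d["cluster_of"], np.array(d["rows"]), d["within_mass"], d["stop_prob"])


def make_clustered_bigram(
    n_clusters: int,
    tokens_per_cluster: int,
    within_mass: float,
    seed: int,
    *,
    stop_prob: float = 0.08,
    concentration: float = 1.0,
) -> ClusteredBigramModel:
    """Build a reproducible clustered bigram model.

    ``within_mass`` must exceed 0.5: clusters have to be sticky for raising the
    temperature to have its intended ground-truth effect (flattening the
    distribution pushes probability across cluster boundaries).

    Word tokens are named ``c<cluster>w<index>`` so they survive the text
    preprocessing pipeline (lowercase, alphanumeric, length >= 2).
    """
    if not (0.5 < within_mass <= 1.0):
        raise ValueError("within_mass must lie in (0.5, 1]: clusters must be sticky")
    if n_clusters < 1 or tokens_per_cluster < 1:
        raise ValueError("cluster counts must be >= 1")
    if not (0.0 <= stop_prob < 1.0):
        raise ValueError("stop_prob must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    words = [f"c{c}w{j}" for c in range(n_clusters) for j in range(tokens_per_cluster)]
    cluster_of = {w: int(w[1 : w.index("w")]) for w in words}
    tokens = tuple(words) + (FULL_STOP, END_OF_TEXT)
    vocab = Vocabulary(tokens)

    v = len(vocab)
    n_words = len(words)
    rows = np.zeros((v, v))
    cluster_id = np.array([cluster_of[w] for w in words])
    for i, w in enumerate(words):
        same = cluster_id == cluster_of[w]
        other = ~same
        word_part = np.zeros(n_words)
        if other.any() and within_mass < 1.0:
            word_part[same] = within_mass * rng.dirichlet(
                np.full(same.sum(), concentration)
            )
            word_part[other] = (1.0 - within_mass) * rng.dirichlet(
                np.full(other.sum(), concentration)
            )
        else:
            # all mass stays in-cluster (absorbing clusters)
            word_part[same] = rng.dirichlet(np.full(same.sum(), concentration))
        rows[i, :n_words] = (1.0 - stop_prob) * word_part
        rows[i, vocab.stop_id] = stop_prob
    # full stop restarts uniformly over words; sentinel row likewise (contexts
    # normally never continue past it)
    for i in (vocab.stop_id, vocab.eot_id):
        rows[i, :n_words] = 1.0 / n_words
    return ClusteredBigramModel(vocab, cluster_of, rows, within_mass, stop_prob)


class TopicWindowModel:
    """Topic-conditional bigram model with window-limited topic inference.

    Every word token belongs to exactly one topic. At each step the model
    infers the active topic mixture from *only the tokens visible in the
    supplied context*: topic weights are proportional to the counts of visible
    word tokens per topic. The next word is drawn from the topic-conditional
    bigram tables mixed by those weights, contaminated by a small ``leakage``
    probability of an unconstrained (uniform over all words) draw.

    Consequences, which make the model a ground truth for the memory-span
    perturbation:

    * with the full history visible, the prompt's topic dominates the counts,
      so narratives stay on topic and drift is slow;
    * with a short window, a handful of leaked off-topic words can flip the
      visible majority, so the topic random-walks away from the prompt —
      while word-to-word transitions remain tightly bound to the local topic.
    """

    def __init__(
        self,
        vocabulary: Vocabulary,
        topic_of: Mapping[str, int],
        tables: Sequence[np.ndarray],
        leakage: float,
        stop_prob: float,
        drift: str = "adjacent",
        drift_uniform_frac: float = 0.0,
        novelty: float = 0.0,
        revisit: float = 0.0,
    ):
        if drift not in ("adjacent", "uniform"):
            raise ValueError("drift must be 'adjacent' or 'uniform'")
        if not (0.0 <= drift_uniform_frac <= 1.0):
            raise ValueError("drift_uniform_frac must lie in [0, 1]")
        if not (0.0 <= novelty < 1.0):
            raise ValueError("novelty must lie in [0, 1)")
        if not (0.0 <= revisit <= 1.0):
            raise ValueError("revisit must lie in [0, 1]")
        self.vocabulary = vocabulary
        self.topic_of = dict(topic_of)
        self.tables = [np.asarray(t, dtype=float) for t in tables]
        self.leakage = float(leakage)
        self.stop_prob = float(stop_prob)
        self.drift = drift
        self.drift_uniform_frac = float(drift_uniform_frac)
        self.novelty = float(novelty)
        self.revisit = float(revisit)
        v = len(vocabulary)
        self.n_topics = len(self.tables)
        self._topic_id = np.full(v, -1, dtype=int)
        for token, tid in self.topic_of.items():
            self._topic_id[vocabulary.index(token)] = tid
        self._word_ids_by_topic = [
            np.flatnonzero(self._topic_id == t) for t in range(self.n_topics)
        ]
        self._word_mask = self._topic_id >= 0
        self._n_words = int(self._word_mask.sum())
        self._uniform = np.full(v, 1.0 / v)
        self._uniform_words = np.zeros(v)
        self._uniform_words[self._word_mask] = 1.0 / self._n_words
        for t, table in enumerate(self.tables):
            if table.shape != (v, len(self._word_ids_by_topic[t])):
                raise ValueError("topic table shape mismatch")
            if np.any(np.abs(table.sum(axis=1) - 1.0) > _PROB_TOL) or np.any(table < 0):
                raise ValueError("topic tables are not valid conditional distributions")
        # leakage target per topic: adjacent topics on the chain (local drift),
        # optionally blended with a uniform component over all words
        # (unstructured drift that seeds global diversity)
        self._leak_rows = np.zeros((self.n_topics, v))
        for t in range(self.n_topics):
            if self.drift == "uniform":
                self._leak_rows[t] = self._uniform_words
                continue
            neighbors = [u for u in (t - 1, t + 1) if 0 <= u < self.n_topics]
            ids = np.concatenate([self._word_ids_by_topic[u] for u in neighbors])
            row = np.zeros(v)
            row[ids] = 1.0 / ids.size
            self._leak_rows[t] = (
                (1.0 - self.drift_uniform_frac) * row
                + self.drift_uniform_frac * self._uniform_words
            )

    # -- topic inference ----------------------------------------------------
    def topic_weights(self, context_ids: Sequence[int]) -> np.ndarray:
        """Topic mixture proportional to visible word-token counts."""
        tids = self._topic_id[np.asarray(context_ids, dtype=int)]
        tids = tids[tids >= 0]
        if tids.size == 0:
            return np.full(self.n_topics, 1.0 / self.n_topics)
        counts = np.bincount(tids, minlength=self.n_topics).astype(float)
        return counts / counts.sum()

    def infer_topic(self, context: Sequence[str]) -> int:
        """Modal topic of the visible context; ties go to the most recent topic."""
        _check_context(context)
        ids = np.asarray(self.vocabulary.to_ids(context), dtype=int)
        ids = ids[ids >= 0]
        tids = self._topic_id[ids] if ids.size else np.array([], dtype=int)
        tids = tids[tids >= 0]
        if tids.size == 0:
            return 0
        counts = np.bincount(tids, minlength=self.n_topics)
        best = counts.max()
        tied = set(np.flatnonzero(counts == best).tolist())
        for t in reversed(tids.tolist()):
            if t in tied:
                return int(t)
        return int(min(tied))

    def example_prompt(self, n_topics: int = 4, words_per_topic: int = 3) -> str:
        """A canonical multi-topic probe prompt: the first few words of each
        of the first ``n_topics`` topics, ending with a full stop.

        Conversational prompts touch several themes at once; seeding the
        context with a small multi-topic core gives the full-memory condition
        a persistent, diverse topical anchor.
        """
        words = []
        for t in range(min(n_topics, self.n_topics)):
            ids = self._word_ids_by_topic[t][:words_per_topic]
            words.extend(self.vocabulary.tokens[i] for i in ids)
        return " ".join(words) + self.vocabulary.full_stop

    # -- backend contract ---------------------------------------------------
    def next_token_distribution(self, context: Sequence[str]) -> TokenDistribution:
        _check_context(context)
        ids = self.vocabulary.to_ids(context)
        return TokenDistribution(self.vocabulary, self._row_ids(ids))

    def _row_ids(self, context_ids: Sequence[int]) -> np.ndarray:
        ids = np.asarray(context_ids, dtype=int)
        known = ids[ids >= 0]
        if known.size == 0:
            return self._uniform
        weights = self.topic_weights(known)
        prev = int(context_ids[-1])
        v = len(self.vocabulary)
        word_part = np.zeros(v)
        leak_part = np.zeros(v)
        for t in np.flatnonzero(weights > 0):
            row = self.tables[t][prev] if prev >= 0 else None
            if row is None:
                word_part[self._word_ids_by_topic[t]] += weights[t] / len(
                    self._word_ids_by_topic[t]
                )
            else:
                word_part[self._word_ids_by_topic[t]] += weights[t] * row
            leak_part += weights[t] * self._leak_rows[t]
        if self.revisit > 0.0:
            # part of the drift mass revisits topics already present in the
            # window: with a long window this makes successive sentences
            # oscillate through the narrative's visited material (so adjacent
            # sentences differ) without extending the drift frontier away
            # from the prompt; with a short window the visited set is just
            # the current topic, so nothing changes
            visited = np.flatnonzero(weights > 0)
            ids = np.concatenate([self._word_ids_by_topic[t] for t in visited])
            revisit_row = np.zeros(v)
            revisit_row[ids] = 1.0 / ids.size
            leak_part = (1.0 - self.revisit) * leak_part + self.revisit * revisit_row
        word_part = (1.0 - self.leakage) * word_part + self.leakage * leak_part
        if self.novelty > 0.0:
            # novelty pressure: words already visible in the window are
            # down-weighted geometrically in their occurrence count, so a long
            # window (where counts accumulate) pushes toward fresh words —
            # the progression a coherent narrative shows — while a short
            # window barely penalizes anything
            counts = np.bincount(known, minlength=v).astype(float)
            penalized = word_part * (1.0 - self.novelty) ** counts
            total = penalized.sum()
            if total > 0.0:  # else everything exhausted: keep unpenalized mix
                word_part = penalized / total
        probs = (1.0 - self.stop_prob) * word_part
        probs[self.vocabulary.stop_id] += self.stop_prob
        return probs

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "topic_window",
                "tokens": list(self.vocabulary.tokens),
                "end_of_text": self.vocabulary.end_of_text,
                "full_stop": self.vocabulary.full_stop,
                "topic_of": self.topic_of,
                "tables": [t.tolist() for t in self.tables],
                "leakage": self.leakage,
                "stop_prob": self.stop_prob,
                "drift": self.drift,
                "drift_uniform_frac": self.drift_uniform_frac,
                "novelty": self.novelty,
                "revisit": self.revisit,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "TopicWindowModel":
        d = json.loads(payload)
        if d.get("kind") != "topic_window":
            raise ValueError("payload does not describe a topic window model")
        vocab = Vocabulary(tuple(d["tokens"]), d["end_of_text"], d["full_stop"])
        return cls(
            vocab,
            d["topic_of"],
            [np.array(t) for t in d["tables"]],
            d["leakage"],
            d["stop_prob"],
            d.get("drift", "adjacent"),
            d.get("drift_uniform_frac", 0.0),
            d.get("novelty", 0.0),
            d.get("revisit", 0.0),
        )


def make_topic_window(
    n_topics: int,
    tokens_per_topic: int,
    seed: int,
    *,
    leakage: float = 0.25,
    stop_prob: float = 0.05,
    concentration: float = 4.0,
    drift: str = "adjacent",
    drift_uniform_frac: float = 0.0,
    novelty: float = 0.0,
    revisit: float = 0.0,
) -> TopicWindowModel:
    """Build a reproducible topic-window model.

    ``leakage`` is the per-word probability of a drift draw; with
    ``drift='adjacent'`` (the default) the drift targets the words of the
    topics neighbouring each active topic on the topic chain, so narratives
    wander through semantically related topics rather than teleporting, and
    ``drift='uniform'`` spreads it over the whole vocabulary instead.
    ``concentration`` controls how even the within-topic bigram rows are
    (larger = closer to uniform).
    """
    if n_topics < 2:
        raise ValueError("need at least 2 topics for topic drift to be observable")
    if tokens_per_topic < 1:
        raise ValueError("tokens_per_topic must be >= 1")
    if not (0.0 <= leakage < 1.0):
        raise ValueError("leakage must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    words = [f"t{t}w{j}" for t in range(n_topics) for j in range(tokens_per_topic)]
    topic_of = {w: int(w[1 : w.index("w")]) for w in words}
    vocab = Vocabulary(tuple(words) + (FULL_STOP, END_OF_TEXT))
    v = len(vocab)
    tables = [
        rng.dirichlet(np.full(tokens_per_topic, concentration), size=v)
        for _ in range(n_topics)
    ]
    return TopicWindowModel(
        vocab, topic_of, tables, leakage, stop_prob, drift, drift_uniform_frac,
        novelty, revisit,
    )


class TransformerBackend:
    """Adapter exposing a pretrained autoregressive transformer as an LMBackend.

    Requires the optional ``transformer`` extra (transformers + torch). The
    model size is configuration — pass any causal-LM identifier, e.g. ``gpt2``
    or ``gpt2-medium``. Never used by the test suite.
    """

    def __init__(self, model_id: str = "gpt2", device: str = "cpu"):
        try:
            import torch  # noqa: F401
            from transformers import AutoModelForCausalLM, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "TransformerBackend requires the 'transformer' extra "
                "(pip install ftdsim[transformer])"
            ) from exc
        self._torch = torch
        self.tokenizer = AutoTokenizer.from_pretrained(model_id)
        self.model = AutoModelForCausalLM.from_pretrained(model_id).to(device).eval()
        self.device = device
        toks = tuple(
            self.tokenizer.convert_ids_to_tokens(range(self.tokenizer.vocab_size))
        )
        self.vocabulary = Vocabulary(
            toks,
            end_of_text=self.tokenizer.eos_token or END_OF_TEXT,
            full_stop=self.tokenizer.tokenize(".")[0],
        )

    def _row_ids(self, context_ids: Sequence[int]) -> np.ndarray:  # pragma: no cover
        torch = self._torch
        ids = torch.tensor([list(context_ids)], device=self.device)
        with torch.no_grad():
            logits = self.model(ids).logits[0, -1]
        probs = torch.softmax(logits, dim=-1).cpu().numpy()
        return probs / probs.sum()

    def next_token_distribution(self, context: Sequence[str]) -> TokenDistribution:  # pragma: no cover
        _check_context(context)
        ids = self.tokenizer.convert_tokens_to_ids(list(context))
        return TokenDistribution(self.vocabulary, self._row_ids(ids))


def load_backend_json(payload: str) -> LMBackend:
    """Deserialize a toy backend from its JSON payload."""
    kind = json.loads(payload).get("kind")
    if kind == "clustered_bigram":
        return ClusteredBigramModel.from_json(payload)
    if kind == "topic_window":
        return TopicWindowModel.from_json(payload)
    raise ValueError(f"unknown backend kind: {kind!r}")
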