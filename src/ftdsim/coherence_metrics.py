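"""Semantic-distance measures of derailment and tangentiality.

Derailment — the loosening of associations between adjacent units of speech —
is operationalized as the cosine distance (1 - cosine similarity) between the
vector embeddings of consecutive (or all pairs of) words or sentences.
Sentences are encoded three ways: the mean of their words' static embeddings,
a relaxed word mover's distance between their word sets, or a contextualized
sentence encoder. Each per-narrative distance series is summarized by its
mean, minimum, maximum, or unbiased sample variance.

Tangentiality — the progressive drift of speech away from the topic — is the
ordinary-least-squares slope of the prompt-to-sentence distance regressed on
sentence index.

To keep the measures semantic rather than repetition-driven, words appearing
in both members of a sentence pair can be excluded before the pair's distance
is computed (on by default, matching common practice). Degenerate pairs —
empty after exclusion, or with a zero mean vector — are skipped and counted,
never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .embeddings import EmbeddingTable, SentenceEncoder, encode_sentence_mean
from .preprocessing import ProcessedNarrative, preprocess

__all__ = [
    "DegenerateVectorError",
    "DistanceSeries",
    "NarrativeMetrics",
    "AGGREGATIONS",
    "cosine_distance",
    "word_distance_series",
    "sentence_distance_static_mean",
    "word_movers_distance",
    "word_movers_distance_exact",
    "sentence_distance_wmd",
    "sentence_distance_contextual",
    "aggregate",
    "prompt_distance_series",
    "tangentiality_slope",
    "compute_narrative_metrics",
]

AGGREGATIONS = ("mean", "min", "max", "variance")

LEVELS = (
    "word_consecutive",
    "word_all_pairs",
    "sentence_consecutive",
    "sentence_all_pairs",
    "sentence_to_prompt",
)


class DegenerateVectorError(ValueError):
    """A vector without direction (zero norm) reached a cosine computation."""


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(u, v), in [0, 2]. Raises on zero vectors (no direction)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must share dimension")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateVectorError("cosine distance undefined for zero vector")
    d = 1.0 - float(np.dot(u, v)) / (nu * nv)
    return min(max(d, 0.0), 2.0)


@dataclass(frozen=True)
class DistanceSeries:
    """Ordered cosine distances at one (level, encoding) combination.

    ``n_skipped`` counts degenerate pairs that were dropped rather than
    imputed (empty after shared-word exclusion, zero mean vector, OOV-empty).
    """

    values: tuple[float, ...]
    level: str
    encoding: str
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        for v in self.values:
            if not (0.0 <= v <= 2.0):
                raise ValueError(f"cosine distance {v!r} outside [0, 2]")

    def __len__(self) -> int:
        return len(self.values)


def _unit_rows(mat: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    return mat / norms


def _pair_indices(n: int, mode: str) -> list[tuple[int, int]]:
    if mode == "consecutive":
        return [(i, i + 1) for i in range(n - 1)]
    if mode == "all_pairs":
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    raise ValueError("mode must be 'consecutive' or 'all_pairs'")


def word_distance_series(
    processed: ProcessedNarrative,
    table: EmbeddingTable,
    mode: str = "consecutive",
    *,
    scope: str = "narrative",
) -> DistanceSeries:
    """Cosine distances between word embeddings.

    ``mode='consecutive'`` links each retained word to the next; OOV words are
    skipped with adjacency re-linked across the gap. ``mode='all_pairs'``
    takes every unordered pair, either across the whole narrative
    (``scope='narrative'``) or within each sentence (``scope='sentence'``).
    Returns an empty series when fewer than 2 in-vocabulary words exist.
    """
    level = "word_consecutive" if mode == "consecutive" else "word_all_pairs"
    if scope == "narrative":
        groups = [processed.word_stream]
    elif scope == "sentence":
        groups = [list(s) for s in processed.sentences_words]
    else:
        raise ValueError("scope must be 'narrative' or 'sentence'")
    values: list[float] = []
    n_skipped = 0
    for words in groups:
        mat, kept = table.matrix(words)
        n_skipped += len(words) - len(kept)
        if len(kept) < 2:
            continue
        unit = _unit_rows(mat)
        if mode == "consecutive":
            sims = np.sum(unit[:-1] * unit[1:], axis=1)
            values.extend(np.clip(1.0 - sims, 0.0, 2.0).tolist())
        else:
            gram = unit @ unit.T
            iu = np.triu_indices(len(kept), k=1)
            values.extend(np.clip(1.0 - gram[iu], 0.0, 2.0).tolist())
    return DistanceSeries(tuple(values), level, "static_mean", n_skipped)


def _exclude_shared(
    words_a: Sequence[str], words_b: Sequence[str]
) -> tuple[list[str], list[str]]:
    set_a, set_b = set(words_a), set(words_b)
    return (
        [w for w in words_a if w not in set_b],
        [w for w in words_b if w not in set_a],
    )


def sentence_distance_static_mean(
    processed: ProcessedNarrative,
    table: EmbeddingTable,
    mode: str = "consecutive",
    *,
    exclude_shared: bool = True,
) -> DistanceSeries:
    """Distance between sentences encoded as the mean of their word vectors.

    Shared-word exclusion is applied per sentence *pair* before encoding.
    Pairs where either sentence becomes empty or encodes to a zero vector are
    skipped and counted.
    """
    level = "sentence_consecutive" if mode == "consecutive" else "sentence_all_pairs"
    sents = [list(s) for s in processed.sentences_words]
    values: list[float] = []
    n_skipped = 0
    for i, j in _pair_indices(len(sents), mode):
        a, b = sents[i], sents[j]
        if exclude_shared:
            a, b = _exclude_shared(a, b)
        va = encode_sentence_mean(a, table) if a else None
        vb = encode_sentence_mean(b, table) if b else None
        if va is None or vb is None:
            n_skipped += 1
            continue
        try:
            values.append(cosine_distance(va, vb))
        except DegenerateVectorError:
            n_skipped += 1
    return DistanceSeries(tuple(values), level, "static_mean", n_skipped)


def word_movers_distance(
    words_a: Sequence[str],
    words_b: Sequence[str],
    table: EmbeddingTable,
    *,
    exclude_shared: bool = True,
) -> float | None:
    """Relaxed, symmetrized word mover's distance between two word lists.

    For each word in one list, the cosine distance to its nearest word in the
    other list; averaged within each direction and then across the two
    directions. Returns None (undefined pair) when either side is empty after
    shared-word exclusion and OOV removal.
    """
    if exclude_shared:
        words_a, words_b = _exclude_shared(words_a, words_b)
    mat_a, kept_a = table.matrix(words_a)
    mat_b, kept_b = table.matrix(words_b)
    if not kept_a or not kept_b:
        return None
    ua, ub = _unit_rows(mat_a), _unit_rows(mat_b)
    dists = np.clip(1.0 - ua @ ub.T, 0.0, 2.0)
    a_to_b = dists.min(axis=1).mean()
    b_to_a = dists.min(axis=0).mean()
    return float((a_to_b + b_to_a) / 2.0)


def word_movers_distance_exact(
    words_a: Sequence[str],
    words_b: Sequence[str],
    table: EmbeddingTable,
    *,
    exclude_shared: bool = False,
) -> float | None:
    """Full optimal-transport word mover's distance with uniform word weights.

    Solves the transportation linear program between the two uniform word
    distributions with cosine-distance costs. Provided as a cross-check for
    the relaxed formulation (each relaxed direction lower-bounds this value).
    """
    from scipy.optimize import linprog

    if exclude_shared:
        words_a, words_b = _exclude_shared(words_a, words_b)
    mat_a, kept_a = table.matrix(words_a)
    mat_b, kept_b = table.matrix(words_b)
    if not kept_a or not kept_b:
        return None
    na, nb = len(kept_a), len(kept_b)
    cost = np.clip(1.0 - _unit_rows(mat_a) @ _unit_rows(mat_b).T, 0.0, 2.0)
    # transportation LP: rows ship 1/na each, columns receive 1/nb each
    a_eq = np.zeros((na + nb, na * nb))
    for i in range(na):
        a_eq[i, i * nb : (i + 1) * nb] = 1.0
    for j in range(nb):
        a_eq[na + j, j::nb] = 1.0
    b_eq = np.concatenate([np.full(na, 1.0 / na), np.full(nb, 1.0 / nb)])
    res = linprog(cost.ravel(), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - tiny dense LPs always solve
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def sentence_distance_wmd(
    processed: ProcessedNarrative,
    table: EmbeddingTable,
    mode: str = "consecutive",
    *,
    exclude_shared: bool = True,
) -> DistanceSeries:
    """Relaxed word mover's distance between sentence pairs."""
    level = "sentence_consecutive" if mode == "consecutive" else "sentence_all_pairs"
    sents = [list(s) for s in processed.sentences_words]
    values: list[float] = []
    n_skipped = 0
    for i, j in _pair_indices(len(sents), mode):
        d = word_movers_distance(sents[i], sents[j], table, exclude_shared=exclude_shared)
        if d is None:
            n_skipped += 1
        else:
            values.append(d)
    return DistanceSeries(tuple(values), level, "wmd", n_skipped)


def sentence_distance_contextual(
    sentences_raw: Sequence[str],
    encoder: SentenceEncoder,
    mode: str = "consecutive",
) -> DistanceSeries:
    """Cosine distances between contextualized sentence encodings."""
    level = "sentence_consecutive" if mode == "consecutive" else "sentence_all_pairs"
    vectors = []
    for k, sent in enumerate(sentences_raw):
        try:
            vectors.append(np.asarray(encoder.encode(sent), dtype=float))
        except Exception as exc:
            raise RuntimeError(f"sentence encoder failed on sentence {k}") from exc
    values = [
        cosine_distance(vectors[i], vectors[j])
        for i, j in _pair_indices(len(vectors), mode)
    ]
    return DistanceSeries(tuple(values), level, "contextual", 0)


def aggregate(series: DistanceSeries | Sequence[float], method: str) -> float | None:
    """Summarize a distance series; None marks an undefined aggregate.

    ``variance`` is the unbiased (n-1) sample variance and needs length >= 2;
    the other methods need a nonempty series.
    """
    values = series.values if isinstance(series, DistanceSeries) else tuple(series)
    if method not in AGGREGATIONS:
        raise ValueError(f"unknown aggregation {method!r}")
    if len(values) == 0:
        return None
    arr = np.asarray(values, dtype=float)
    if method == "mean":
        return float(arr.mean())
    if method == "min":
        return float(arr.min())
    if method == "max":
        return float(arr.max())
    if len(values) < 2:
        return None
    return float(arr.var(ddof=1))


def prompt_distance_series(
    prompt_text: str,
    processed: ProcessedNarrative,
    *,
    table: EmbeddingTable | None = None,
    encoder: SentenceEncoder | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Prompt-to-sentence distances d_k with their 1-based sentence indices.

    The prompt is encoded as one unit (it is the topic referent). With a
    static ``table``, the prompt and every sentence are encoded as mean word
    vectors of their processed words; with a contextual ``encoder``, raw
    strings are encoded directly. Degenerate sentences are skipped but their
    indices are preserved. Returns (k, d, n_skipped).
    """
    if (table is None) == (encoder is None):
        raise ValueError("supply exactly one of table= or encoder=")
    ks: list[int] = []
    ds: list[float] = []
    n_skipped = 0
    if encoder is not None:
        prompt_vec = np.asarray(encoder.encode(prompt_text), dtype=float)
        sentence_vecs: list[np.ndarray | None] = [
            np.asarray(encoder.encode(s), dtype=float) for s in processed.sentences_raw
        ]
    else:
        prompt_words = preprocess(prompt_text).word_stream
        prompt_vec = encode_sentence_mean(prompt_words, table)
        if prompt_vec is None or not np.any(prompt_vec):
            raise DegenerateVectorError("prompt has no usable embedding")
        sentence_vecs = [
            encode_sentence_mean(list(s), table) for s in processed.sentences_words
        ]
    for k, vec in enumerate(sentence_vecs, start=1):
        if vec is None:
            n_skipped += 1
            continue
        try:
            ds.append(cosine_distance(prompt_vec, vec))
            ks.append(k)
        except DegenerateVectorError:
            n_skipped += 1
    return np.asarray(ks, dtype=float), np.asarray(ds, dtype=float), n_skipped


def tangentiality_slope(
    prompt_text: str,
    processed: ProcessedNarrative,
    *,
    table: EmbeddingTable | None = None,
    encoder: SentenceEncoder | None = None,
) -> tuple[float, float] | None:
    """(slope, first_distance) of prompt-to-sentence distance over sentence index.

    The slope is the OLS slope of d_k on k (distance units per sentence);
    first_distance is d_1 (or the first valid d). Returns None when fewer
    than 2 valid distances exist.
    """
    ks, ds, _ = prompt_distance_series(prompt_text, processed, table=table, encoder=encoder)
    if len(ds) < 2 or np.ptp(ks) == 0:
        return None
    slope = float(np.polyfit(ks, ds, 1)[0])
    return slope, float(ds[0])


@dataclass(frozen=True)
class NarrativeMetrics:
    """Flattened per-narrative metric map.

    Keys follow ``level|encoding|aggregation`` (e.g.
    ``sentence_consecutive|contextual|mean``) plus
    ``tangentiality_slope|<encoding>`` and
    ``first_sentence_distance|<encoding>``. Undefined metrics are absent.
    """

    values: dict[str, float]
    mean_words_per_sentence: float
    n_sentences: int
    oov_rate: float = 0.0


def compute_narrative_metrics(
    processed: ProcessedNarrative,
    prompt_text: str,
    *,
    table: EmbeddingTable | None = None,
    encoder: SentenceEncoder | None = None,
    aggregations: Sequence[str] = AGGREGATIONS,
    modes: Sequence[str] = ("consecutive", "all_pairs"),
    exclude_shared: bool = True,
    word_scope: str = "narrative",
) -> NarrativeMetrics:
    """All selected derailment and tangentiality metrics for one narrative.

    Word-level series use the static table only; sentence-level series are
    computed for every encoding whose backend (table / encoder) was supplied.
    """
    values: dict[str, float] = {}

    def put(series: DistanceSeries) -> None:
        for agg in aggregations:
            v = aggregate(series, agg)
            if v is not None:
                values[f"{series.level}|{series.encoding}|{agg}"] = v

    oov = 0.0
    if table is not None:
        oov = table.oov_rate(processed.word_stream)
        for mode in modes:
            put(word_distance_series(processed, table, mode, scope=word_scope))
            put(sentence_distance_static_mean(processed, table, mode, exclude_shared=exclude_shared))
            put(sentence_distance_wmd(processed, table, mode, exclude_shared=exclude_shared))
        res = tangentiality_slope(prompt_text, processed, table=table)
        if res is not None:
            values["tangentiality_slope|static_mean"] = res[0]
            values["first_sentence_distance|static_mean"] = res[1]
    if encoder is not None:
        for mode in modes:
            put(sentence_distance_contextual(processed.sentences_raw, encoder, mode))
        res = tangentiality_slope(prompt_text, processed, encoder=encoder)
        if res is not None:
            values["tangentiality_slope|contextual"] = res[0]
            values["first_sentence_distance|contextual"] = res[1]
    return NarrativeMetrics(
        values=values,
        mean_words_per_sentence=processed.mean_words_per_sentence,
        n_sentences=len(processed.sentences_raw),
        oov_rate=oov,
    )
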