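"""Perturbed autoregressive decoding.

Narratives are generated token by token from an :class:`~ftdsim.lm_backend.LMBackend`
under two theory-driven perturbations:

* **temperature** — the next-token distribution is flattened (probabilities are
  raised to the power 1/T and renormalized), modelling a generalized
  under-constraint of word selection;
* **memory span** — only the most recent ``memory_span`` tokens of the full
  history are presented to the backend at each step, modelling an impaired use
  of global context.

Decoding further applies the conventions that make generated text realistic:
beam-search sampling (several multi-token candidate trajectories, committing
the first token of the highest-joint-probability one), exclusion of the
lowest-probability tail by cumulative mass, a no-repeat n-gram constraint, and
an explicit token ban list.

The per-step constraint order follows canonical decoder implementations:
forbidden-token masking -> temperature -> tail exclusion -> renormalize ->
sample. Masking first keeps the ban absolute (zeros survive every later
transform) and makes the zero-temperature limit coincide exactly with greedy
argmax decoding of the constrained distribution. If the mask empties the
distribution, the step falls back to the unconstrained tempered distribution
and logs a warning.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .lm_backend import LMBackend, TokenDistribution

__all__ = [
    "GenerationConfig",
    "Narrative",
    "apply_temperature",
    "truncate_context",
    "exclude_probability_tail",
    "forbidden_next_tokens",
    "beam_extend",
    "generate_narrative",
    "tokenize",
    "detokenize",
    "write_narratives_jsonl",
    "read_narratives_jsonl",
    "narratives_to_csv",
]

logger = logging.getLogger(__name__)

# default ban list: web artifacts an autoregressive model trained on internet
# text tends to emit; user-extensible via GenerationConfig.banned_tokens
DEFAULT_BANNED_TOKENS = frozenset({"https://", "http://", "www", "\n", "\n\n", "\t"})

_NO_ATTACH_LEFT = {".", ",", "!", "?", ";", ":", ")", "]", "'", "''"}


@dataclass(frozen=True)
class GenerationConfig:
    """All decoding knobs for one narrative.

    ``temperature`` (dimensionless, > 0) and ``memory_span`` (tokens, >= 1)
    are the two perturbations; the remaining fields are the fixed decoding
    conventions: 200-token narratives, 5 beams of 3-token lookahead, exclusion
    of the lowest 1% of probability mass, a no-repeat-2-gram constraint and a
    ban list of internet-artifact tokens.
    """

    temperature: float = 1.0
    memory_span: int = 200
    max_tokens: int = 200
    n_beams: int = 5
    lookahead: int = 3
    tail_exclusion_mass: float = 0.01
    tail_mode: str = "mass"  # "mass": nucleus by cumulative mass; "count": drop lowest fraction of entries
    no_repeat_ngram: int | None = 2
    banned_tokens: frozenset[str] = DEFAULT_BANNED_TOKENS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.memory_span < 1:
            raise ValueError("memory_span must be >= 1")
        if self.n_beams < 1 or self.lookahead < 1:
            raise ValueError("n_beams and lookahead must be >= 1")
        if not (0.0 <= self.tail_exclusion_mass < 1.0):
            raise ValueError("tail_exclusion_mass must lie in [0, 1)")
        if self.no_repeat_ngram is not None and self.no_repeat_ngram < 2:
            raise ValueError("no_repeat_ngram must be >= 2 (or None to disable)")
        if self.tail_mode not in ("mass", "count"):
            raise ValueError("tail_mode must be 'mass' or 'count'")
        object.__setattr__(self, "banned_tokens", frozenset(self.banned_tokens))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["banned_tokens"] = sorted(self.banned_tokens)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenerationConfig":
        d = dict(d)
        d["banned_tokens"] = frozenset(d.get("banned_tokens", ()))
        return cls(**d)


@dataclass(frozen=True)
class Narrative:
    """One generated narrative plus everything needed to regenerate it."""

    prompt_id: str
    prompt_text: str
    config: GenerationConfig
    tokens: tuple[str, ...]
    text: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "prompt_id": self.prompt_id,
            "prompt_text": self.prompt_text,
            "config": self.config.to_dict(),
            "tokens": list(self.tokens),
            "text": self.text,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Narrative":
        return cls(
            prompt_id=d["prompt_id"],
            prompt_text=d["prompt_text"],
            config=GenerationConfig.from_dict(d["config"]),
            tokens=tuple(d["tokens"]),
            text=d["text"],
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# elementary decoding transforms
# ---------------------------------------------------------------------------

def _temper(probs: np.ndarray, temperature: float) -> np.ndarray:
    """probs ** (1/T), renormalized; computed in log space for stability.

    Accepts an unnormalized nonnegative vector and always returns a
    normalized one.
    """
    if temperature == 1.0:
        return probs / probs.sum()
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    logp = logp / temperature
    logp -= logp.max()
    out = np.exp(logp)
    return out / out.sum()


def apply_temperature(dist: TokenDistribution, temperature: float) -> TokenDistribution:
    """Flatten (T > 1) or sharpen (T < 1) a token distribution.

    Output probabilities are proportional to the input probabilities raised to
    the power 1/temperature. T = 1 is the identity; as T -> 0 the distribution
    concentrates on its argmax; as T -> inf it approaches uniform over the
    support.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if temperature == 1.0:
        return TokenDistribution(dist.vocabulary, dist.probs.copy())
    return TokenDistribution(dist.vocabulary, _temper(dist.probs, temperature))


def truncate_context(tokens: Sequence[str], memory_span: int) -> list[str]:
    """Keep only the last ``memory_span`` tokens (order preserved)."""
    if memory_span < 1:
        raise ValueError("memory_span must be >= 1")
    return list(tokens[-memory_span:])


def _exclude_tail(probs: np.ndarray, tail_mass: float, mode: str = "mass") -> np.ndarray:
    """Zero out the low-probability tail and renormalize.

    mode="mass": remove the smallest-probability tokens whose cumulative mass
    is <= tail_mass (nucleus rule with retained mass 1 - tail_mass).
    mode="count": remove the lowest tail_mass fraction of positive-probability
    entries (by count).
    """
    if tail_mass == 0.0:
        return probs
    support = np.flatnonzero(probs > 0)
    if support.size == 0:
        raise ValueError("cannot exclude tail of an empty distribution")
    order = support[np.argsort(probs[support], kind="stable")]
    if mode == "mass":
        cum = np.cumsum(probs[order])
        n_drop = int(np.searchsorted(cum, tail_mass, side="right"))
    else:
        n_drop = int(np.floor(tail_mass * support.size))
    if n_drop >= support.size:
        raise ValueError("tail exclusion would remove all tokens")
    if n_drop == 0:
        return probs
    out = probs.copy()
    out[order[:n_drop]] = 0.0
    return out / out.sum()


def exclude_probability_tail(
    dist: TokenDistribution, tail_mass: float, *, mode: str = "mass"
) -> TokenDistribution:
    """Drop the lowest-probability tokens whose cumulative mass is <= tail_mass."""
    if not (0.0 <= tail_mass < 1.0):
        raise ValueError("tail_mass must lie in [0, 1)")
    return TokenDistribution(dist.vocabulary, _exclude_tail(dist.probs, tail_mass, mode))


def forbidden_next_tokens(
    generated: Sequence[str], n: int, banned: Iterable[str]
) -> set[str]:
    """Tokens that may not follow ``generated``.

    Returns the ban list plus every token that would recreate an n-gram already
    present in the sequence (prompt + generated tokens concatenated).
    """
    if n < 2:
        raise ValueError("n-gram order must be >= 2")
    forbidden = set(banned)
    if len(generated) >= n - 1:
        prefix = tuple(generated[-(n - 1):])
        for i in range(len(generated) - n + 1):
            if tuple(generated[i : i + n - 1]) == prefix:
                forbidden.add(generated[i + n - 1])
    return forbidden


# ---------------------------------------------------------------------------
# the decoding loop (id-level fast path)
# ---------------------------------------------------------------------------


class _NgramIndex:
    """Incremental (n-1)-prefix -> {next ids} index over the committed sequence."""

    def __init__(self, n: int | None, ids: Sequence[int]):
        self.n = n
        self.table: dict[tuple[int, ...], set[int]] = {}
        if n is not None:
            for i in range(len(ids) - n + 1):
                self.table.setdefault(tuple(ids[i : i + n - 1]), set()).add(ids[i + n - 1])

    def add(self, ids: Sequence[int]) -> None:
        """Register the n-gram ending at the last element of ``ids``."""
        n = self.n
        if n is None or len(ids) < n:
            return
        self.table.setdefault(tuple(ids[-n:-1]), set()).add(ids[-1])

    def forbidden(self, ids: Sequence[int], extra: Sequence[Sequence[int]] = ()) -> set[int]:
        """Ids forbidden after ``ids``; ``extra`` supplies hypothetical n-grams."""
        n = self.n
        if n is None or len(ids) < n - 1:
            return set()
        prefix = tuple(ids[-(n - 1):]) if n > 1 else ()
        out = set(self.table.get(prefix, ()))
        for seq in extra:
            for i in range(len(seq) - n + 1):
                if tuple(seq[i : i + n - 1]) == prefix:
                    out.add(seq[i + n - 1])
        return out


def _sample(probs: np.ndarray, rng: np.random.Generator) -> int:
    cum = np.cumsum(probs)
    return int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))


def _step_distribution(
    row: np.ndarray,
    config: GenerationConfig,
    forbidden_ids: set[int],
) -> np.ndarray:
    """Apply forbidden masking -> temperature -> tail exclusion -> renormalize."""
    if forbidden_ids:
        masked = row.copy()
        masked[list(forbidden_ids)] = 0.0
        if masked.sum() <= 0.0:
            logger.warning(
                "all candidate tokens forbidden; falling back to unconstrained "
                "tempered distribution"
            )
            return _temper(row, config.temperature)
        row = masked
    p = _temper(row, config.temperature)
    return _exclude_tail(p, config.tail_exclusion_mass, config.tail_mode)


def _beam_extend_ids(
    backend: LMBackend,
    history_ids: list[int],
    config: GenerationConfig,
    rng: np.random.Generator,
    ngrams: _NgramIndex,
    banned_ids: frozenset[int],
) -> int:
    """Commit one token: sample n_beams lookahead trajectories, return the
    first token of the highest-joint-probability one (ties -> first beam)."""
    eot = backend.vocabulary.eot_id
    nn = ngrams.n
    best_logp = -np.inf
    best_first = -1
    for _ in range(config.n_beams):
        hyp: list[int] = []
        logp = 0.0
        for _step in range(config.lookahead):
            seq = history_ids + hyp
            row = backend._row_ids(seq[-config.memory_span:])
            forb = set(banned_ids)
            if nn is not None and len(seq) >= nn - 1:
                prefix = tuple(seq[-(nn - 1):])
                forb |= ngrams.table.get(prefix, set())
                if hyp:  # n-grams formed by this beam's hypothetical tokens
                    start = max(0, len(history_ids) - nn + 1)
                    for i in range(start, len(seq) - nn + 1):
                        if tuple(seq[i : i + nn - 1]) == prefix:
                            forb.add(seq[i + nn - 1])
            p = _step_distribution(row, config, forb)
            tok = _sample(p, rng)
            logp += float(np.log(p[tok]))
            hyp.append(tok)
            if tok == eot:
                break
        if logp > best_logp:
            best_logp = logp
            best_first = hyp[0]
    return best_first


def beam_extend(
    backend: LMBackend,
    context: Sequence[str],
    config: GenerationConfig,
    rng: np.random.Generator,
) -> str:
    """Choose the next token after ``context`` by beam-search sampling.

    Builds ``config.n_beams`` candidate trajectories of ``config.lookahead``
    tokens each by ancestral sampling from the tempered, tail-excluded,
    constraint-masked distributions, and returns the first token of the
    trajectory with the highest joint probability under the processed
    distributions. The backend sees only the last ``memory_span`` tokens; the
    no-repeat constraint scans the full supplied context.
    """
    if len(context) == 0:
        raise ValueError("context must be non-empty")
    vocab = backend.vocabulary
    ids = vocab.to_ids(context)
    ngrams = _NgramIndex(config.no_repeat_ngram, ids)
    banned_ids = frozenset(
        vocab.index(t) for t in config.banned_tokens if t in vocab
    )
    tok = _beam_extend_ids(backend, list(ids), config, rng, ngrams, banned_ids)
    return vocab.tokens[tok]


def _step_rng(seed: int, step: int) -> np.random.Generator:
    # per-step generator derived by counter: narratives are independent of the
    # order in which a sweep generates them
    return np.random.default_rng(np.random.SeedSequence([seed, step]))


def generate_narrative(
    backend: LMBackend,
    prompt: str,
    config: GenerationConfig,
    *,
    prompt_id: str = "prompt",
) -> Narrative:
    """Generate one narrative: truncate history to ``memory_span``, extend by
    beam-search sampling, repeat until ``max_tokens`` tokens are generated or
    the end-of-text sentinel is emitted.

    A pure function of (backend, prompt, config): the same inputs always yield
    a bit-identical narrative.
    """
    prompt_tokens = tokenize(prompt)
    if not prompt_tokens:
        raise ValueError("prompt must tokenize to at least one token")
    vocab = backend.vocabulary
    history = vocab.to_ids(prompt_tokens)
    ngrams = _NgramIndex(config.no_repeat_ngram, history)
    banned_ids = frozenset(
        vocab.index(t) for t in config.banned_tokens if t in vocab
    )
    generated: list[str] = []
    for step in range(config.max_tokens):
        rng = _step_rng(config.seed, step)
        tok = _beam_extend_ids(backend, history, config, rng, ngrams, banned_ids)
        history.append(tok)
        ngrams.add(history)
        token = vocab.tokens[tok]
        if tok == vocab.eot_id:
            break
        generated.append(token)
    return Narrative(
        prompt_id=prompt_id,
        prompt_text=prompt,
        config=config,
        tokens=tuple(generated),
        text=detokenize(generated),
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# tokenization helpers and narrative IO
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"<\|endoftext\|>|\w+(?:'\w+)?|[^\w\s]")


def tokenize(text: str) -> list[str]:
    """Whitespace/punctuation tokenizer used for prompts and toy narratives."""
    return _TOKEN_RE.findall(text)


def detokenize(tokens: Sequence[str]) -> str:
    """Deterministic inverse of :func:`tokenize` up to spacing conventions:
    punctuation attaches to the preceding token."""
    parts: list[str] = []
    for tok in tokens:
        if parts and tok in _NO_ATTACH_LEFT:
            parts[-1] += tok
        else:
            parts.append(tok)
    return " ".join(parts)


def write_narratives_jsonl(narratives: Iterable[Narrative], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for narr in narratives:
            fh.write(json.dumps(narr.to_dict()) + "\n")


def read_narratives_jsonl(path: str | Path) -> list[Narrative]:
    out = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(Narrative.from_dict(json.loads(line)))
    return out


def narratives_to_csv(narratives: Iterable[Narrative], path: str | Path) -> None:
    """One row per narrative: text plus flattened config columns."""
    path = Path(path)
    rows = []
    for narr in narratives:
        row = {
            "prompt_id": narr.prompt_id,
            "prompt_text": narr.prompt_text,
            "seed": narr.seed,
            "n_tokens": len(narr.tokens),
            "text": narr.text,
        }
        for k, v in narr.config.to_dict().items():
            row[f"config_{k}"] = ";".join(v) if isinstance(v, list) else v
        rows.append(row)
    if not rows:
        raise ValueError("no narratives to write")
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
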