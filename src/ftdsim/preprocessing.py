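"""Text normalization applied before any semantic-distance computation.

The pipeline mirrors conventional practice for coherence analysis of speech
transcripts: narratives are split into sentences on full stops, common
contractions are expanded, and — for static-embedding analyses only — each
sentence is tokenized into words, lowercased, stripped of stop words, single
letters and non-alphanumeric material, and lemmatized. Raw sentence strings
are kept alongside the word lists because contextualized sentence encoders
consume unfiltered sentences.

The stop-word list, contraction table and dictionary lemmatizer are bundled,
versioned data files so results are reproducible without any model download;
all three are replaceable by the caller.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Mapping

__all__ = [
    "ProcessedNarrative",
    "DictionaryLemmatizer",
    "SpacyLemmatizer",
    "split_sentences",
    "expand_contractions",
    "tokenize_and_filter",
    "preprocess",
    "load_stop_words",
    "load_contraction_table",
    "default_lemmatizer",
]

Lemmatizer = Callable[[str], str]


def _data_text(name: str) -> str:
    return resources.files("ftdsim.data").joinpath(name).read_text(encoding="utf-8")


def load_stop_words() -> frozenset[str]:
    """The bundled stop-word list (lowercase)."""
    words = []
    for line in _data_text("stopwords.txt").splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            words.append(line)
    return frozenset(words)


def load_contraction_table() -> dict[str, str]:
    """The bundled contraction -> expansion table (lowercase keys)."""
    reader = csv.DictReader(_data_text("contractions.csv").splitlines())
    return {row["contraction"].lower(): row["expansion"] for row in reader}


class DictionaryLemmatizer:
    """Lookup lemmatizer backed by a form -> lemma dictionary.

    Unknown forms map to themselves. Chains in the supplied table are resolved
    at construction so that the mapping is idempotent (lemma(lemma(w)) ==
    lemma(w)), which the whole preprocessing pipeline relies on.
    """

    def __init__(self, table: Mapping[str, str] | None = None):
        if table is None:
            reader = csv.DictReader(_data_text("lemmas.csv").splitlines())
            table = {row["form"].lower(): row["lemma"].lower() for row in reader}
        resolved: dict[str, str] = {}
        for form, lemma in table.items():
            seen = {form}
            while lemma in table and lemma not in seen:
                seen.add(lemma)
                lemma = table[lemma]
            resolved[form] = lemma
        self.table = resolved

    def __call__(self, word: str) -> str:
        return self.table.get(word, word)


class SpacyLemmatizer:
    """Adapter to a full statistical lemmatizer (optional ``nlp`` extra)."""

    def __init__(self, model: str = "en_core_web_sm"):
        try:
            import spacy
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "SpacyLemmatizer requires the 'nlp' extra (pip install ftdsim[nlp])"
            ) from exc
        self.nlp = spacy.load(model, disable=["parser", "ner"])  # pragma: no cover

    def __call__(self, word: str) -> str:  # pragma: no cover - optional dependency
        doc = self.nlp(word)
        return doc[0].lemma_.lower() if len(doc) else word


_default_lemmatizer: DictionaryLemmatizer | None = None


def default_lemmatizer() -> DictionaryLemmatizer:
    global _default_lemmatizer
    if _default_lemmatizer is None:
        _default_lemmatizer = DictionaryLemmatizer()
    return _default_lemmatizer


@dataclass(frozen=True)
class ProcessedNarrative:
    """Preprocessed view of one narrative.

    ``sentences_raw`` keeps the original sentence strings (input to contextual
    encoders); ``sentences_words`` holds the lemmatized content words of each
    sentence (input to static-embedding metrics). ``word_stream`` is their
    in-order concatenation.
    """

    sentences_raw: tuple[str, ...]
    sentences_words: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(self.sentences_raw) != len(self.sentences_words):
            raise ValueError("sentence lists must be parallel")

    @property
    def word_stream(self) -> list[str]:
        return [w for sent in self.sentences_words for w in sent]

    @property
    def mean_words_per_sentence(self) -> float:
        if not self.sentences_words:
            return 0.0
        return sum(len(s) for s in self.sentences_words) / len(self.sentences_words)

    def to_json(self) -> str:
        return json.dumps(
            {
                "sentences_raw": list(self.sentences_raw),
                "sentences_words": [list(s) for s in self.sentences_words],
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "ProcessedNarrative":
        d = json.loads(payload)
        return cls(
            tuple(d["sentences_raw"]),
            tuple(tuple(s) for s in d["sentences_words"]),
        )


_SENTENCE_RE = re.compile(r"[^.]+\.+|[^.]+")
_WORD_RE = re.compile(r"[a-z0-9]+")
_APOSTROPHES = str.maketrans({"’": "'", "‘": "'"})


def split_sentences(text: str) -> list[str]:
    """Split on full stops; runs of consecutive stops form one boundary.

    Terminal punctuation is retained in each sentence string and whitespace-only
    segments are dropped. Abbreviations are not protected: a full stop always
    ends a sentence.
    """
    return [m.strip() for m in _SENTENCE_RE.findall(text) if m.strip()]


def expand_contractions(text: str, table: Mapping[str, str] | None = None) -> str:
    """Expand every contraction in ``table`` (case-preserving on the first letter)."""
    if table is None:
        table = load_contraction_table()
    text = text.translate(_APOSTROPHES)
    pattern = re.compile(
        r"\b(" + "|".join(re.escape(k) for k in sorted(table, key=len, reverse=True)) + r")\b",
        re.IGNORECASE,
    )

    def repl(match: re.Match[str]) -> str:
        original = match.group(0)
        expansion = table[original.lower()]
        if original[0].isupper():
            return expansion[0].upper() + expansion[1:]
        return expansion

    return pattern.sub(repl, text)


def tokenize_and_filter(
    sentence: str,
    stop_words: Iterable[str] | None = None,
    lemmatizer: Lemmatizer | None = None,
) -> list[str]:
    """Lowercase, drop stop words / single letters / non-alphanumerics, lemmatize.

    The stop-word and length filters are re-applied after lemmatization so
    that no output word violates them (a lemma can be shorter than its form or
    collide with a stop word).
    """
    stops = frozenset(stop_words) if stop_words is not None else load_stop_words()
    lemma = lemmatizer if lemmatizer is not None else default_lemmatizer()
    out: list[str] = []
    for raw in _WORD_RE.findall(sentence.lower()):
        if len(raw) < 2 or raw in stops:
            continue
        word = lemma(raw)
        if len(word) < 2 or word in stops or not word.isalnum():
            continue
        out.append(word)
    return out


def preprocess(
    text: str,
    *,
    stop_words: Iterable[str] | None = None,
    lemmatizer: Lemmatizer | None = None,
    contraction_table: Mapping[str, str] | None = None,
) -> ProcessedNarrative:
    """Full pipeline: sentence split -> contraction expansion -> word filtering."""
    stops = frozenset(stop_words) if stop_words is not None else load_stop_words()
    lemma = lemmatizer if lemmatizer is not None else default_lemmatizer()
    sentences = [
        expand_contractions(s, contraction_table) for s in split_sentences(text)
    ]
    words = tuple(
        tuple(tokenize_and_filter(s, stops, lemma)) for s in sentences
    )
    return ProcessedNarrative(tuple(sentences), words)
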