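"""Field-tagged, IDF-weighted, binary-term cosine similarity between records.

Each of the five scored fields (concatenated title, condition, intervention,
outcome, inclusion criteria) gets its own index: a term's weight in a field
is ``ln(N / df)``, where ``N`` is the number of indexed records and ``df``
the number of records whose field contains the term.  Terms are *binary*
(repeats within a field count once), but the same word in two different
fields is two distinct features.  Stop words and punctuation-only tokens
have weight exactly zero.  Redacted records vectorize to the empty vector,
so their similarity to anything is zero.
"""

from __future__ import annotations

import math
import re
import unicodedata
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Sequence

from .corpus import RegistryRecord
from .stopwords import ENGLISH_STOP_WORDS

__all__ = [
    "SCORED_FIELDS",
    "normalize_text",
    "tokenize",
    "FieldIndex",
    "FeatureVector",
    "build_field_index",
    "build_indexes",
    "vectorize",
    "cosine",
]

#: The five fields considered for similarity scoring.  ``title`` is the
#: concatenation of public title, scientific title, and acronym.
SCORED_FIELDS = ("title", "condition", "intervention", "outcome", "inclusion")

_KEEP = frozenset(
    "abcdefghijklmnopqrstuvwxyz0123456789 "
    "!\"#$%&'()*+,-./:;<=>?@[\\]^_`{|}~"
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def normalize_text(raw: str) -> str:
    """Case-fold, strip accents, and reduce to Latin letters, digits,
    punctuation and single spaces.

    Characters with no Latin transliteration (via NFKD decomposition) are
    replaced by spaces.  The function is idempotent.
    """
    text = unicodedata.normalize("NFKD", raw.casefold())
    text = "".join(c for c in text if not unicodedata.combining(c))
    text = "".join(c if c in _KEEP else " " for c in text)
    return " ".join(text.split())


def tokenize(norm_text: str) -> list[str]:
    """Split normalized text into words: maximal runs of ``[a-z0-9]``.

    All other characters are boundaries, so punctuation-only tokens never
    appear.
    """
    return _TOKEN_RE.findall(norm_text)


def _terms(raw: str) -> set[str]:
    return set(tokenize(normalize_text(raw)))


@dataclass
class FieldIndex:
    """Per-field document frequencies and the derived IDF weights."""

    field: str
    doc_count: int
    doc_freq: dict[str, int]
    stop_terms: frozenset[str] = ENGLISH_STOP_WORDS

    def weight(self, term: str) -> float:
        """``ln(N / df)`` for indexed non-stop terms; 0 otherwise.

        A term absent from the index has no defined document frequency and
        gets weight 0 rather than an extrapolated one.
        """
        if term in self.stop_terms:
            return 0.0
        df = self.doc_freq.get(term, 0)
        if df == 0:
            return 0.0
        return math.log(self.doc_count / df)

    # -- serialization (documented key-value dump, versioned) ---------------

    def to_dict(self) -> dict:
        return {
            "format": "trialdedup-field-index/1",
            "field": self.field,
            "doc_count": self.doc_count,
            "doc_freq": dict(self.doc_freq),
            "stop_terms": sorted(self.stop_terms),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "FieldIndex":
        if data.get("format") != "trialdedup-field-index/1":
            raise ValueError(f"unknown index format {data.get('format')!r}")
        return cls(
            field=data["field"],
            doc_count=data["doc_count"],
            doc_freq=dict(data["doc_freq"]),
            stop_terms=frozenset(data["stop_terms"]),
        )


@dataclass
class FeatureVector:
    """A record's weighted, field-tagged term set.

    ``entries`` maps ``(field, term)`` to its IDF weight; presence is
    binary, so a term repeated within a field contributes a single entry.
    """

    entries: dict[tuple[str, str], float] = dc_field(default_factory=dict)

    @property
    def norm(self) -> float:
        return math.sqrt(sum(w * w for w in self.entries.values()))


def build_field_index(
    corpus: Sequence[RegistryRecord],
    field: str,
    stop_terms: frozenset[str] = ENGLISH_STOP_WORDS,
) -> FieldIndex:
    """Compute binary per-record document frequencies for one field."""
    if not corpus:
        raise ValueError("cannot build an index over an empty corpus")
    if field not in SCORED_FIELDS:
        raise KeyError(f"unknown field {field!r}; expected one of {SCORED_FIELDS}")
    df: dict[str, int] = {}
    for rec in corpus:
        for term in _terms(rec.field_text(field)):
            df[term] = df.get(term, 0) + 1
    return FieldIndex(field=field, doc_count=len(corpus), doc_freq=df,
                      stop_terms=stop_terms)


def build_indexes(
    corpus: Sequence[RegistryRecord],
    fields: Iterable[str] = SCORED_FIELDS,
) -> dict[str, FieldIndex]:
    return {f: build_field_index(corpus, f) for f in fields}


def vectorize(
    record: RegistryRecord,
    indexes: Mapping[str, FieldIndex],
    fields: Iterable[str] | None = None,
) -> FeatureVector:
    """Build the binary, field-tagged, IDF-weighted vector of a record.

    Redacted records (and records whose normalized text is empty in every
    requested field) yield the empty vector.
    """
    if record.redacted:
        return FeatureVector()
    if fields is None:
        fields = list(indexes)
    entries: dict[tuple[str, str], float] = {}
    for f in fields:
        idx = indexes[f]
        for term in _terms(record.field_text(f)):
            w = idx.weight(term)
            if w > 0.0:
                entries[(f, term)] = w
    return FeatureVector(entries)


def cosine(a: FeatureVector, b: FeatureVector) -> float:
    """Cosine similarity of two feature vectors, in [0, 1].

    0 if either vector is empty (covers redacted records); 1 iff the
    records contain exactly the same set of words in the same fields.
    """
    na, nb = a.norm, b.norm
    if na == 0.0 or nb == 0.0:
        return 0.0
    small, large = (a.entries, b.entries) if len(a.entries) <= len(b.entries) \
        else (b.entries, a.entries)
    dot = 0.0
    for key, w in small.items():
        w2 = large.get(key)
        if w2 is not None:
            dot += w * w2
    return min(dot / (na * nb), 1.0)
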