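"""Known-duplicate grouping via secondary-ID linkage.

Registries let sponsors list other identifiers for a trial in a free-text
secondary-ID field.  When such an identifier equals the registry ID of
another record, the two records can be grouped as *known duplicates* of
each other; grouping is the transitive closure of those matches, so every
record in a group is a known duplicate of every other.  This module
reproduces that grouping and adds two corroboration experiments: matching
WHO Universal Trial Numbers (UTNs) shared between records, and matching an
externally supplied sponsor identifier list against sponsor-filtered
records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

from .corpus import RegistryRecord, euctr_stem

__all__ = [
    "IdToken",
    "DuplicateGroupSet",
    "TrialCounts",
    "tokenize_secondary_ids",
    "match_ids_to_records",
    "build_groups",
    "link_corpus",
    "count_unique_trials",
    "known_pairs",
    "match_by_utn",
    "match_external_id_list",
    "DEFAULT_ID_STOP_LIST",
]

# separators inside the secondary-ID field: whitespace and , ; .
_SEP_RE = re.compile(r"[\s,;.]+")

_EUDRACT_RE = re.compile(r"^\d{4}-\d{6}-\d{2}$")
_UTN_RE = re.compile(r"^u1111-\d{4}-\d{4}$")

#: Tokens that never produce linkage edges.  The field is full of filler
#: values ("Nil known", "Version 1"); tokens shorter than 4 characters are
#: also rejected as too likely to collide by chance.
DEFAULT_ID_STOP_LIST = frozenset({
    "nil", "none", "known", "unknown", "pending", "n/a", "version",
    "protocol", "study", "trial", "number",
})

MIN_TOKEN_LEN = 4


@dataclass(frozen=True, slots=True)
class IdToken:
    """A whitespace/``,;.``-free token extracted from a secondary-ID value."""

    text: str
    source_record: str


def tokenize_secondary_ids(
    raw_ids: Iterable[str], source_record: str = ""
) -> list[IdToken]:
    """Split raw secondary-ID strings into tokens.

    A single field value may carry several identifiers; every maximal run
    of characters not in ``{whitespace , ; .}`` becomes one token.  Note
    that "." is a separator, so identifiers with internal dots are split.
    """
    tokens: list[IdToken] = []
    for raw in raw_ids:
        for part in _SEP_RE.split(raw):
            if part:
                tokens.append(IdToken(text=part, source_record=source_record))
    return tokens


def corpus_id_tokens(corpus: Sequence[RegistryRecord]) -> list[IdToken]:
    """Tokens from the secondary IDs of all variants of every record."""
    out: list[IdToken] = []
    for rec in corpus:
        out.extend(tokenize_secondary_ids(rec.secondary_ids, rec.record_id))
    return out


def _id_index(corpus: Sequence[RegistryRecord]) -> dict[str, str]:
    """Case-folded lookup from id spellings to record ids.

    EUCTR records are reachable by full variant id, by their stem, and by
    the bare EudraCT number (the EUCTR prefix and member-state code may
    both be absent in references).
    """
    index: dict[str, str] = {}
    for rec in corpus:
        index[rec.record_id.casefold()] = rec.record_id
        for v in rec.variants:
            index[v.registry_id.casefold()] = rec.record_id
        stem, _ = euctr_stem(rec.variants[0].registry_id)
        if stem.startswith("EUCTR") and _EUDRACT_RE.match(stem[5:]):
            index[stem[5:].casefold()] = rec.record_id
    return index


def match_ids_to_records(
    tokens: Iterable[IdToken],
    corpus: Sequence[RegistryRecord],
    stop_list: frozenset[str] = DEFAULT_ID_STOP_LIST,
    min_token_len: int = MIN_TOKEN_LEN,
) -> list[tuple[str, str, str]]:
    """Match secondary-ID tokens to registry IDs.

    Comparison is case-insensitive after trimming.  For most registries an
    exact match is required; for EUCTR the prefix and/or the member-state
    code may be absent.  Self-matches are discarded; edges are canonical
    (smaller record id first) and deduplicated.
    """
    index = _id_index(corpus)
    edges: dict[tuple[str, str], str] = {}
    for tok in tokens:
        text = tok.text.strip().casefold()
        if len(text) < min_token_len or text in stop_list:
            continue
        target = index.get(text)
        if target is None or target == tok.source_record:
            continue
        a, b = sorted((tok.source_record, target))
        edges.setdefault((a, b), "secondary_id")
    return [(a, b, reason) for (a, b), reason in sorted(edges.items())]


@dataclass
class DuplicateGroupSet:
    """A partition of record ids into known-duplicate groups.

    Groups are the connected components of the match edges; unmatched
    records form singleton groups.  The number of groups is the assumed
    number of unique trials.
    """

    groups: list[frozenset[str]]
    edge_reasons: dict[tuple[str, str], str] = field(default_factory=dict)
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {
                rid: gi for gi, grp in enumerate(self.groups) for rid in grp
            }

    def group_of(self, record_id: str) -> int:
        return self._index[record_id]

    def same_group(self, a: str, b: str) -> bool:
        return self._index.get(a) == self._index.get(b) and a in self._index

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def build_groups(
    edges: Iterable[tuple[str, str, str]],
    corpus: Sequence[RegistryRecord] | Iterable[str],
) -> DuplicateGroupSet:
    """Connected components over all records; singletons for the unmatched."""
    record_ids = [
        r.record_id if isinstance(r, RegistryRecord) else r for r in corpus
    ]
    g = nx.Graph()
    g.add_nodes_from(record_ids)
    reasons: dict[tuple[str, str], str] = {}
    for a, b, reason in edges:
        if a not in g or b not in g:
            raise KeyError(f"edge ({a}, {b}) references an unknown record")
        g.add_edge(a, b)
        key = (a, b) if a < b else (b, a)
        reasons.setdefault(key, reason)
    groups = sorted(
        (frozenset(c) for c in nx.connected_components(g)), key=min
    )
    return DuplicateGroupSet(groups=groups, edge_reasons=reasons)


def link_corpus(
    corpus: Sequence[RegistryRecord],
    stop_list: frozenset[str] = DEFAULT_ID_STOP_LIST,
) -> DuplicateGroupSet:
    """Tokenize all secondary IDs, match them, and build the grouping."""
    tokens = corpus_id_tokens(corpus)
    edges = match_ids_to_records(tokens, corpus, stop_list=stop_list)
    return build_groups(edges, corpus)


@dataclass(frozen=True)
class TrialCounts:
    unique_trials: int
    records_with_duplicates: int
    group_size_histogram: dict[int, int]


def count_unique_trials(groups: DuplicateGroupSet) -> TrialCounts:
    """Number of groups (= unique trials), plus diagnostics."""
    hist: dict[int, int] = {}
    with_dups = 0
    for grp in groups.groups:
        size = len(grp)
        hist[size] = hist.get(size, 0) + 1
        if size >= 2:
            with_dups += size
    return TrialCounts(
        unique_trials=groups.n_groups,
        records_with_duplicates=with_dups,
        group_size_histogram=dict(sorted(hist.items())),
    )


def known_pairs(groups: DuplicateGroupSet) -> set[tuple[str, str]]:
    """All unordered within-group pairs (sum over groups of C(size, 2))."""
    pairs: set[tuple[str, str]] = set()
    for grp in groups.groups:
        for a, b in combinations(sorted(grp), 2):
            pairs.add((a, b))
    return pairs


def match_by_utn(corpus: Sequence[RegistryRecord]) -> list[tuple[str, str, str]]:
    """Edges between records sharing a WHO Universal Trial Number.

    UTNs have the shape ``U1111-dddd-dddd``; a UTN held by a single record
    yields no edge.
    """
    holders: dict[str, list[str]] = {}
    for tok in corpus_id_tokens(corpus):
        text = tok.text.strip().casefold()
        if _UTN_RE.match(text):
            lst = holders.setdefault(text, [])
            if tok.source_record not in lst:
                lst.append(tok.source_record)
    edges: set[tuple[str, str]] = set()
    for records in holders.values():
        for a, b in combinations(sorted(records), 2):
            edges.add((a, b))
    return [(a, b, "utn") for a, b in sorted(edges)]


def _norm_name(name: str) -> str:
    return " ".join(name.casefold().split())


def match_external_id_list(
    corpus: Sequence[RegistryRecord],
    ids: Sequence[str],
    sponsor_names: Sequence[str],
) -> tuple[list[tuple[str, str, str]], int]:
    """Match an external identifier list against sponsor-filtered records.

    Only records whose sponsor field contains one of ``sponsor_names``
    (case-insensitive substring after whitespace normalization) are
    eligible.  Returns the implied new edges (records sharing an external
    id, reason ``external_list``) and the count of matched secondary-ID
    tokens.
    """
    if not ids:
        return [], 0
    wanted = {i.strip().casefold() for i in ids if i.strip()}
    names = [_norm_name(n) for n in sponsor_names if n.strip()]
    holders: dict[str, list[str]] = {}
    matched = 0
    for rec in corpus:
        sponsor_text = _norm_name(" ".join(rec.sponsors))
        if not any(n in sponsor_text for n in names):
            continue
        seen_here: set[str] = set()
        for tok in tokenize_secondary_ids(rec.secondary_ids, rec.record_id):
            text = tok.text.strip().casefold()
            if text in wanted and text not in seen_here:
                seen_here.add(text)
                matched += 1
                lst = holders.setdefault(text, [])
                if rec.record_id not in lst:
                    lst.append(rec.record_id)
    edges: set[tuple[str, str]] = set()
    for records in holders.values():
        for a, b in combinations(sorted(records), 2):
            edges.add((a, b))
    return [(a, b, "external_list") for a, b in sorted(edges)], matched
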