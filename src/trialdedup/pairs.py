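"""Lossless thresholded similarity join over record titles.

Finding every record pair whose title similarity meets a threshold cannot
afford the full n(n-1)/2 comparisons at registry scale, but the sieve must
be *lossless*: a pair may only be skipped when a provable upper bound on
its score is below the threshold.  Since cosine over non-negative weights
is positive only when the two records share at least one non-zero-weight
term, candidate generation through a term-sharing inverted index (realized
here as a sparse matrix product over L2-normalized vectors, computed in row
blocks to bound memory) provably returns the exact thresholded pair set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .corpus import RegistryRecord
from .linkage import DuplicateGroupSet
from .similarity import FieldIndex, _terms

__all__ = [
    "ScoredPair",
    "ScoreRange",
    "default_ranges",
    "all_pairs_above",
    "count_total_comparisons",
    "partition_known",
    "range_histogram",
]


@dataclass(slots=True)
class ScoredPair:
    """A canonical unordered record pair (``id_a < id_b``) with its score."""

    id_a: str
    id_b: str
    score: float
    known: bool | None = None

    def __post_init__(self) -> None:
        if not self.id_a < self.id_b:
            raise ValueError("pair must be canonical: id_a < id_b")


@dataclass(frozen=True, slots=True)
class ScoreRange:
    """Half-open score range with the convention ``lo < x <= hi``."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("require lo < hi")

    def contains(self, score: float) -> bool:
        return self.lo < score <= self.hi

    def __str__(self) -> str:
        return f"{self.lo:g}<x<={self.hi:g}"


def default_ranges(lo: float = 0.5, hi: float = 1.0, step: float = 0.1) -> list[ScoreRange]:
    """Contiguous ranges partitioning (lo, hi], e.g. (0.5,0.6] ... (0.9,1.0]."""
    edges = np.round(np.arange(lo, hi + step / 2, step), 10)
    return [ScoreRange(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def count_total_comparisons(n: int) -> int:
    """Number of pair-wise comparisons among n records: n(n-1)/2, exact."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n - 1) // 2


def title_matrix(
    corpus: Sequence[RegistryRecord], index: FieldIndex
) -> tuple[list[str], sparse.csr_matrix]:
    """L2-normalized record-by-term weight matrix for the indexed field.

    Rows follow the lexicographic order of record ids so that an upper-
    triangular pair (i < j) is already canonical.  Redacted records get an
    all-zero row.
    """
    corpus = sorted(corpus, key=lambda r: r.record_id)
    ids = [r.record_id for r in corpus]
    term_col: dict[str, int] = {}
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    for i, rec in enumerate(corpus):
        if rec.redacted:
            continue
        for term in _terms(rec.field_text(index.field)):
            w = index.weight(term)
            if w > 0.0:
                col = term_col.setdefault(term, len(term_col))
                rows.append(i)
                cols.append(col)
                data.append(w)
    mat = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(ids), max(len(term_col), 1))
    )
    norms = np.sqrt(np.asarray(mat.multiply(mat).sum(axis=1)).ravel())
    inv = np.divide(1.0, norms, out=np.zeros_like(norms), where=norms > 0)
    mat = sparse.diags(inv) @ mat
    return ids, mat.tocsr()


def _head_matrix(mat: sparse.csr_matrix, threshold: float) -> sparse.csr_matrix:
    """Per-row *head* pattern for the prefix filter.

    Within each L2-normalized row, terms are ordered by descending weight;
    the lowest-weight terms form the row's *tail*, grown greedily while the
    tail's norm stays below the threshold (minus a small safety margin for
    float rounding).  The remaining head carries the guarantee: if two rows
    share no term belonging to either head, their dot product is at most
    ``||tail|| * 1 < threshold``, so the pair can be skipped losslessly.
    High-frequency terms have low IDF weight and land in tails, which is
    what makes the candidate product cheap.
    """
    cut2 = max(threshold - 1e-9, 0.0) ** 2
    indptr, indices, data = mat.indptr, mat.indices, mat.data
    keep = np.ones(len(indices), dtype=bool)
    for i in range(mat.shape[0]):
        lo, hi = indptr[i], indptr[i + 1]
        if lo == hi:
            continue
        w = data[lo:hi]
        order = np.argsort(w)  # ascending: tail candidates first
        tail2 = 0.0
        for k in order:
            tail2 += w[k] * w[k]
            if tail2 >= cut2:
                break
            keep[lo + k] = False
    head = mat.copy()
    head.data = keep.astype(np.float64)
    head.eliminate_zeros()
    head.data[:] = 1.0
    return head


def all_pairs_above(
    corpus: Sequence[RegistryRecord],
    index: FieldIndex,
    threshold: float,
) -> list[ScoredPair]:
    """Every record pair with cosine similarity >= threshold on the indexed
    field — exactly (pairs scoring precisely at the threshold included).

    Candidate generation is an inverted-index product restricted by a
    weight-ordered prefix filter (see :func:`_head_matrix`): a comparison is
    skipped only when a provable upper bound on the pair's score is below
    the threshold, so the result equals exhaustive enumeration.

    Parameters
    ----------
    corpus, index
        Consolidated records and the field index to score against
        (operationally the title index).
    threshold
        Must be in (0, 1]; a non-positive threshold would enumerate all
        n(n-1)/2 pairs and is rejected.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ids, mat = title_matrix(corpus, index)
    n = len(ids)
    if n < 2:
        return []
    full = mat.copy()
    full.data = np.ones_like(full.data)
    head = _head_matrix(mat, threshold)
    # (i, j) is a candidate iff the pair shares a term in head(i) or head(j)
    cand = (full @ head.T).tocoo()
    ii = np.minimum(cand.row, cand.col)
    jj = np.maximum(cand.row, cand.col)
    keep = ii < jj
    pairs_ij = np.unique(np.stack([ii[keep], jj[keep]], axis=1), axis=0)
    if len(pairs_ij) == 0:
        return []
    # exact scores for the candidates only
    scores = np.asarray(
        mat[pairs_ij[:, 0]].multiply(mat[pairs_ij[:, 1]]).sum(axis=1)
    ).ravel()
    out = [
        ScoredPair(ids[i], ids[j], float(min(s, 1.0)))
        for (i, j), s in zip(pairs_ij, scores)
        if s >= threshold
    ]
    out.sort(key=lambda p: (p.id_a, p.id_b))
    return out


def partition_known(
    pairs: Iterable[ScoredPair], groups: DuplicateGroupSet
) -> tuple[list[ScoredPair], list[ScoredPair]]:
    """Split scored pairs into known duplicates (same group) and candidates.

    Sets the ``known`` flag on each pair in place and returns
    ``(known_pairs, candidate_pairs)``.
    """
    known: list[ScoredPair] = []
    candidates: list[ScoredPair] = []
    for p in pairs:
        p.known = groups.same_group(p.id_a, p.id_b)
        (known if p.known else candidates).append(p)
    return known, candidates


def range_histogram(
    pairs: Iterable[ScoredPair], ranges: Sequence[ScoreRange]
) -> pd.DataFrame:
    """Per-range pair counts (total, known, candidate).

    Every pair must fall into exactly one range (``lo < score <= hi``); a
    score outside all ranges indicates a threshold/range mismatch and is an
    error.  Pairs whose ``known`` flag is unset count as candidates.
    """
    ranges = sorted(ranges, key=lambda r: r.lo)
    for a, b in zip(ranges[:-1], ranges[1:]):
        if a.hi > b.lo:
            raise ValueError("ranges must be disjoint")
    total = [0] * len(ranges)
    known = [0] * len(ranges)
    for p in pairs:
        for i, r in enumerate(ranges):
            if r.contains(p.score):
                total[i] += 1
                if p.known:
                    known[i] += 1
                break
        else:
            raise ValueError(
                f"pair ({p.id_a}, {p.id_b}) score {p.score} outside all ranges")
    return pd.DataFrame({
        "lo": [r.lo for r in ranges],
        "hi": [r.hi for r in ranges],
        "total": total,
        "known": known,
        "candidate": [t - k for t, k in zip(total, known)],
    })
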