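"""End-to-end convenience pipeline: link, score, sample, rate, estimate.

Glue over the individual modules, used by the command-line interface and
by simulation studies: consolidate a corpus, build the known-duplicate
grouping, run the lossless title-similarity join, draw stratified samples
of candidate pairs, obtain ratings (from a human ratings table, the rule
engine, or a truth oracle), and fit the hidden-duplicate model.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import pandas as pd

from .corpus import RecordVariant, RegistryRecord, consolidate_variants
from .estimation import (HiddenDuplicateModel, HiddenDuplicateResults,
                         RangeSample, sample_candidates)
from .linkage import DuplicateGroupSet, known_pairs, link_corpus
from .pairs import (ScoredPair, ScoreRange, all_pairs_above, default_ranges,
                    partition_known, range_histogram)
from .similarity import build_field_index

__all__ = [
    "score_title_pairs",
    "estimate_hidden",
    "run_pipeline",
    "observational_summary",
]

Rater = Callable[[str, str], str]


def score_title_pairs(
    records: Sequence[RegistryRecord],
    threshold: float = 0.5,
) -> list[ScoredPair]:
    """Lossless title-similarity join at the given threshold."""
    index = build_field_index(records, "title")
    return all_pairs_above(records, index, threshold)


def estimate_hidden(
    records: Sequence[RegistryRecord],
    groups: DuplicateGroupSet,
    pairs: list[ScoredPair],
    rater: Rater,
    *,
    ranges: Sequence[ScoreRange] | None = None,
    sample_size: int = 150,
    seed: int = 0,
    conf: float = 0.95,
    coverage: float | None = None,
) -> HiddenDuplicateResults:
    """Sample candidates per range, rate them, and fit the model.

    Per range, ``min(sample_size, pool)`` candidate pairs are drawn without
    replacement (seeded per range) and rated by ``rater``; ratings of
    ``"unknown"`` count as non-duplicates, mirroring the doubt rule.
    Coverage defaults to the fraction of known-duplicate pairs that fall
    inside the examined ranges.
    """
    if ranges is None:
        ranges = default_ranges()
    _, candidates = partition_known(pairs, groups)
    hist = range_histogram(pairs, ranges)
    total_known = len(known_pairs(groups))

    samples: list[RangeSample] = []
    kept_ranges: list[ScoreRange] = []
    for i, r in enumerate(ranges):
        pool = int(hist.loc[(hist["lo"] == r.lo) & (hist["hi"] == r.hi),
                            "candidate"].iloc[0])
        if pool == 0:
            continue
        s = sample_candidates(candidates, r, min(sample_size, pool),
                              seed=seed + i)
        s.x = sum(1 for p in s.pairs if rater(p.id_a, p.id_b) == "duplicate")
        samples.append(s)
        kept_ranges.append(r)
    if not samples:
        raise ValueError("no candidate pairs in any examined range")

    model = HiddenDuplicateModel.from_samples(
        samples, hist,
        total_known_pairs=total_known,
        n_unique_trials=groups.n_groups,
        coverage=coverage,
    )
    return model.fit(conf=conf)


def run_pipeline(
    variants: Iterable[RecordVariant],
    rater: Rater,
    *,
    threshold: float = 0.5,
    ranges: Sequence[ScoreRange] | None = None,
    sample_size: int = 150,
    seed: int = 0,
    conf: float = 0.95,
) -> HiddenDuplicateResults:
    """Full pipeline from raw variants to a fitted hidden-duplicate model."""
    records = consolidate_variants(variants)
    groups = link_corpus(records)
    pairs = score_title_pairs(records, threshold)
    return estimate_hidden(records, groups, pairs, rater, ranges=ranges,
                           sample_size=sample_size, seed=seed, conf=conf)


def observational_summary(
    records: Sequence[RegistryRecord],
    groups: DuplicateGroupSet,
    pairs: Sequence[ScoredPair],
) -> pd.Series:
    """Corpus-level descriptive figures for comparison against an archived
    registry snapshot: record counts, known-pair counts, pairs at or above
    the join threshold, and the known-pair title-score distribution.

    Purely observational; the values depend on the dataset supplied.
    """
    kp = known_pairs(groups)
    pair_scores = {(p.id_a, p.id_b): p.score for p in pairs}
    known_scores = pd.Series(
        [pair_scores.get(k, 0.0) for k in sorted(kp)], dtype=float)
    return pd.Series({
        "records": len(records),
        "unique_trials": groups.n_groups,
        "known_pairs": len(kp),
        "pairs_scored": len(pairs),
        "median_known_title_score": (
            float(known_scores.median()) if len(known_scores) else float("nan")),
        "fraction_known_above_threshold": (
            float((known_scores > 0.5).mean()) if len(known_scores) else float("nan")),
    })
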