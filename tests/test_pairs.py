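"""Thresholded similarity join: exactness, partitioning, histograms."""

from __future__ import annotations

import numpy as np
import pytest

from trialdedup.corpus import consolidate_variants
from trialdedup.linkage import link_corpus
from trialdedup.pairs import (ScoredPair, ScoreRange, all_pairs_above,
                              count_total_comparisons, default_ranges,
                              partition_known, range_histogram)
from trialdedup.similarity import build_field_index, cosine, vectorize
from trialdedup.synthetic import generate_corpus, ictrp_like

from conftest import make_record


def brute_force_pairs(records, index, threshold):
    """Exhaustive all-pairs enumeration through the scalar cosine path."""
    vecs = {r.record_id: vectorize(r, {"title": index}, ["title"])
            for r in records}
    ids = sorted(vecs)
    out = set()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            s = cosine(vecs[ids[i]], vecs[ids[j]])
            if s >= threshold:
                out.add((ids[i], ids[j]))
    return out


@pytest.mark.parametrize("threshold", [0.3, 0.5, 0.7])
def test_join_equals_brute_force(threshold, small_corpus):
    _, records, _ = small_corpus
    records = records[:250]
    index = build_field_index(records, "title")
    got = {(p.id_a, p.id_b) for p in all_pairs_above(records, index, threshold)}
    assert got == brute_force_pairs(records, index, threshold)


def test_identical_titles_all_pairs_at_one():
    # background records keep the shared title terms at df < N, so their
    # IDF weight is positive and identical vectors score exactly 1
    records = [make_record(f"NCT0000000{i}", public_title="same exact title words")
               for i in range(5)]
    records += [make_record(f"NCT0000001{i}", public_title=f"background{i} noise{i}")
                for i in range(3)]
    index = build_field_index(records, "title")
    pairs = all_pairs_above(records, index, 0.5)
    assert len(pairs) == count_total_comparisons(5) == 10
    assert all(p.score == pytest.approx(1.0) for p in pairs)


def test_disjoint_vocabulary_no_pairs():
    records = [make_record(f"NCT0000000{i}", public_title=f"word{i} term{i}")
               for i in range(4)]
    index = build_field_index(records, "title")
    assert all_pairs_above(records, index, 0.3) == []


def test_threshold_monotonicity(small_corpus):
    _, records, _ = small_corpus
    index = build_field_index(records, "title")
    lo = {(p.id_a, p.id_b) for p in all_pairs_above(records, index, 0.5)}
    hi = {(p.id_a, p.id_b) for p in all_pairs_above(records, index, 0.7)}
    assert hi <= lo


def test_nonpositive_threshold_rejected(small_corpus):
    _, records, _ = small_corpus
    index = build_field_index(records, "title")
    with pytest.raises(ValueError):
        all_pairs_above(records, index, 0.0)


@pytest.mark.parametrize("n,expected", [
    (0, 0), (2, 1), (10, 45), (285_177, 40_662_818_076),
])
def test_count_total_comparisons(n, expected):
    assert count_total_comparisons(n) == expected


def test_partition_known_conservation(small_corpus):
    _, records, truth = small_corpus
    groups = link_corpus(records)
    index = build_field_index(records, "title")
    pairs = all_pairs_above(records, index, 0.5)
    known, candidates = partition_known(pairs, groups)
    assert len(known) + len(candidates) == len(pairs)
    truth_pairs = truth.duplicate_pairs()
    for p in known:
        assert truth_pairs.get((p.id_a, p.id_b)) is True  # planted known
    # planted hidden duplicates are candidates, never "known"
    hidden = {k for k, flag in truth_pairs.items() if not flag}
    assert {(p.id_a, p.id_b) for p in known}.isdisjoint(hidden)


def test_range_boundary_convention():
    ranges = [ScoreRange(0.7, 0.8), ScoreRange(0.8, 0.9)]
    pairs = [ScoredPair("A", "B", 0.8, known=False)]
    hist = range_histogram(pairs, ranges)
    assert hist.loc[0, "total"] == 1      # 0.8 falls in (0.7, 0.8]
    assert hist.loc[1, "total"] == 0


def test_histogram_conservation_and_recount(small_corpus):
    _, records, _ = small_corpus
    groups = link_corpus(records)
    index = build_field_index(records, "title")
    pairs = all_pairs_above(records, index, 0.5)
    partition_known(pairs, groups)
    ranges = default_ranges()
    hist = range_histogram(pairs, ranges)
    assert hist["total"].sum() == len(pairs)
    assert (hist["total"] == hist["known"] + hist["candidate"]).all()
    # independent recount
    for _, row in hist.iterrows():
        n = sum(1 for p in pairs if row["lo"] < p.score <= row["hi"])
        assert n == row["total"]


def test_score_outside_ranges_is_error():
    with pytest.raises(ValueError, match="outside"):
        range_histogram([ScoredPair("A", "B", 0.4)], [ScoreRange(0.5, 1.0)])


def test_known_fraction_rises_with_score(small_corpus):
    """Qualitatively, high score ranges are dominated by known duplicates
    more than the lowest range (planted corpora)."""
    _, records, _ = small_corpus
    groups = link_corpus(records)
    index = build_field_index(records, "title")
    pairs = all_pairs_above(records, index, 0.3)
    partition_known(pairs, groups)
    ranges = [ScoreRange(0.3, 0.5), ScoreRange(0.5, 1.0)]
    hist = range_histogram(pairs, ranges)
    frac = hist["known"] / hist["total"]
    assert frac.iloc[1] > frac.iloc[0]


def test_lossless_on_random_corpora_quick():
    """Spot-check of the lossless contract on a couple of fresh corpora
    (the broader sweep lives in the acceptance suite)."""
    for seed in (3, 4):
        params = ictrp_like(seed=seed, n_trials=120, vocab_size=250)
        variants, _ = generate_corpus(params)
        records = consolidate_variants(variants)
        index = build_field_index(records, "title")
        for thr in (0.3, 0.7):
            got = {(p.id_a, p.id_b, round(p.score, 9))
                   for p in all_pairs_above(records, index, thr)}
            vecs = {r.record_id: vectorize(r, {"title": index}, ["title"])
                    for r in records}
            ids = sorted(vecs)
            want = set()
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    s = cosine(vecs[ids[i]], vecs[ids[j]])
                    if s >= thr:
                        want.add((ids[i], ids[j], round(s, 9)))
            assert got == want
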