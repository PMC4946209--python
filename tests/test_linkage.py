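"""Secondary-ID linkage: tokenization, matching, grouping, corroboration."""

from __future__ import annotations

import random

import pytest

from trialdedup.corpus import euctr_stem
from trialdedup.linkage import (DuplicateGroupSet, build_groups,
                                corpus_id_tokens, count_unique_trials,
                                known_pairs, link_corpus, match_by_utn,
                                match_external_id_list, match_ids_to_records,
                                tokenize_secondary_ids)

from conftest import make_record


@pytest.mark.parametrize("raw,expected", [
    (["NCT01472939; 2011-004388-62"], ["NCT01472939", "2011-004388-62"]),
    (["Version 1"], ["Version", "1"]),
    ([], []),
    (["a.b,c;d e"], ["a", "b", "c", "d", "e"]),
    (["  ", ";;,."], []),
])
def test_tokenize_secondary_ids(raw, expected):
    assert [t.text for t in tokenize_secondary_ids(raw, "R")] == expected


@pytest.fixture()
def linked_corpus():
    return [
        make_record("NCT01472939", secondary_ids=("2011-004388-62",)),
        make_record("EUCTR2011-004388-62-BE", registry="EUCTR"),
        make_record("NCT99999990", secondary_ids=("NCT99999999",)),
        make_record("ISRCTN12345678"),
    ]


def test_match_bare_eudract_number(linked_corpus):
    tokens = corpus_id_tokens(linked_corpus)
    edges = match_ids_to_records(tokens, linked_corpus)
    assert edges == [("EUCTR2011-004388-62", "NCT01472939", "secondary_id")]


def test_match_full_euctr_variant_id_resolves_to_stem(linked_corpus):
    tokens = tokenize_secondary_ids(["EUCTR2011-004388-62-BE"], "NCT01472939")
    edges = match_ids_to_records(tokens, linked_corpus)
    assert [(a, b) for a, b, _ in edges] == [("EUCTR2011-004388-62", "NCT01472939")]


def test_match_missing_target_yields_no_edge(linked_corpus):
    tokens = tokenize_secondary_ids(["NCT99999999"], "NCT99999990")
    assert match_ids_to_records(tokens, linked_corpus[:2]) == []


def test_nonsense_guard_blocks_short_and_stop_tokens():
    corpus = [
        make_record("NCT00000001", secondary_ids=("nil", "A1")),
        make_record("nil"),  # pathological registry id equal to a stop word
        make_record("A1"),
    ]
    tokens = corpus_id_tokens(corpus)
    assert match_ids_to_records(tokens, corpus) == []


def test_match_equals_brute_force_scan(small_corpus):
    """Index-based matching agrees with an exhaustive (token, record) scan."""
    _, records, _ = small_corpus
    tokens = corpus_id_tokens(records)
    edges = match_ids_to_records(tokens, records)

    spellings = {}  # record -> all id spellings that should match it
    for rec in records:
        forms = {rec.record_id.casefold()}
        for v in rec.variants:
            forms.add(v.registry_id.casefold())
        stem, _suffix = euctr_stem(rec.variants[0].registry_id)
        if stem.startswith("EUCTR"):
            forms.add(stem[5:].casefold())
        spellings[rec.record_id] = forms
    from trialdedup.linkage import DEFAULT_ID_STOP_LIST, MIN_TOKEN_LEN
    brute = set()
    for tok in tokens:
        text = tok.text.strip().casefold()
        if len(text) < MIN_TOKEN_LEN or text in DEFAULT_ID_STOP_LIST:
            continue
        for rid, forms in spellings.items():
            if text in forms and rid != tok.source_record:
                brute.add(tuple(sorted((tok.source_record, rid))))
    assert {(a, b) for a, b, _ in edges} == brute


def test_groups_are_transitive_closure():
    corpus = ["A", "B", "C", "D", "E"]
    groups = build_groups([("A", "B", "secondary_id"),
                           ("B", "C", "secondary_id")], corpus)
    assert frozenset({"A", "B", "C"}) in groups.groups
    assert groups.n_groups == 3  # {A,B,C}, {D}, {E}
    assert groups.same_group("A", "C") and not groups.same_group("A", "D")


def test_no_edges_all_singletons():
    groups = build_groups([], ["A", "B", "C"])
    assert groups.n_groups == 3
    assert all(len(g) == 1 for g in groups.groups)


def test_grouping_invariant_to_edge_and_record_order():
    rng = random.Random(5)
    edges = [("A", "B", "x"), ("C", "D", "x"), ("B", "C", "x"), ("E", "F", "x")]
    records = ["A", "B", "C", "D", "E", "F", "G"]
    ref = build_groups(edges, records).groups
    for _ in range(5):
        e = edges[:]
        r = records[:]
        rng.shuffle(e)
        rng.shuffle(r)
        assert set(build_groups(e, r).groups) == set(ref)


def test_count_identity_and_histogram(small_corpus):
    _, records, _ = small_corpus
    groups = link_corpus(records)
    counts = count_unique_trials(groups)
    total = sum(len(g) for g in groups.groups)
    assert total == len(records)
    # unique trials + sum(size - 1) == records
    extra = sum((s - 1) * c for s, c in counts.group_size_histogram.items())
    assert counts.unique_trials + extra == len(records)


def test_known_pairs_counts():
    groups = DuplicateGroupSet(groups=[frozenset("ABC"),
                                       frozenset("DEFGHIJKLM"),
                                       frozenset("Z")])
    pairs = known_pairs(groups)
    assert len(pairs) == 3 + 45
    assert ("A", "B") in pairs and all(a < b for a, b in pairs)


def test_recovers_planted_known_clusters_exactly(small_corpus):
    """ID linkage alone recovers the planted known clusters: precision and
    recall are both 1 against the truth labels."""
    _, records, truth = small_corpus
    groups = link_corpus(records)
    recovered = {g for g in groups.groups if len(g) >= 2}
    assert recovered == set(truth.known_clusters())


def test_match_by_utn():
    corpus = [
        make_record("DRKS00005274", secondary_ids=("U1111-1147-8393",)),
        make_record("NCT02139163", secondary_ids=("U1111-1147-8393",)),
        make_record("NCT02139164", secondary_ids=("U1111-9999-0000",)),
        make_record("NCT02139165", secondary_ids=("U1111-12-3",)),
    ]
    edges = match_by_utn(corpus)
    assert edges == [("DRKS00005274", "NCT02139163", "utn")]


def test_external_id_list_requires_sponsor_match():
    corpus = [
        make_record("NCT00000010", secondary_ids=("GSK-10001",),
                    sponsors=("GlaxoSmithKline",)),
        make_record("ISRCTN00000011", secondary_ids=("GSK-10001",),
                    sponsors=("glaxosmithkline plc",)),
        make_record("NCT00000012", secondary_ids=("GSK-10001",),
                    sponsors=("Pfizer",)),  # id present, sponsor absent
        make_record("NCT00000013", secondary_ids=("GSK-10002",),
                    sponsors=("GlaxoSmithKline",)),
    ]
    edges, matched = match_external_id_list(
        corpus, ["GSK-10001", "GSK-10002"], ["GlaxoSmithKline"])
    assert matched == 3
    assert edges == [("ISRCTN00000011", "NCT00000010", "external_list")]
    assert match_external_id_list(corpus, [], ["GlaxoSmithKline"]) == ([], 0)


def test_external_id_list_matches_brute_force_cross_join(small_corpus):
    """Sponsor-filtered external-ID matching agrees with a full cross-join."""
    _, records, _ = small_corpus
    # use planted protocol ids of one sponsor as the "external" list
    sponsor = records[0].sponsors[0]
    ext_ids = sorted({
        t.text for r in records for t in tokenize_secondary_ids(r.secondary_ids)
        if "-" in t.text and t.text[:3].isalpha()
    })[:50]
    edges, matched = match_external_id_list(records, ext_ids, [sponsor])

    wanted = {i.casefold() for i in ext_ids}
    eligible = [r for r in records
                if sponsor.casefold() in " ".join(r.sponsors).casefold()]
    brute_matches = 0
    holders: dict[str, set[str]] = {}
    for r in eligible:
        toks = {t.text.casefold() for t in tokenize_secondary_ids(r.secondary_ids)}
        hits = toks & wanted
        brute_matches += len(hits)
        for h in hits:
            holders.setdefault(h, set()).add(r.record_id)
    brute_edges = set()
    for members in holders.values():
        for a in members:
            for b in members:
                if a < b:
                    brute_edges.add((a, b))
    assert matched == brute_matches
    assert {(a, b) for a, b, _ in edges} == brute_edges
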