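"""Rule-based duplicate adjudication and ratings import/export.

Registry summaries are too thin to prove that two records describe the
same trial, so judgments rely on an ordered set of signals.  This module
encodes those signals as a deterministic rule engine, evaluated in fixed
precedence:

1. near-identical titles containing contradictory phrases (e.g. "fed
   conditions" vs "fasting conditions"), or an extension-study phrase on
   exactly one side -> non-duplicate;
2. shared sponsor and a shared secondary-ID token that is long enough not
   to collide by chance and is not a US federal grant number (grant
   numbers recur across many unrelated trials) -> duplicate;
3. shared sponsor but distinct secondary IDs in the same format (same
   length and letter/digit skeleton, typical of incrementing protocol
   numbers) -> non-duplicate;
4. sufficiently similar fields with no contradictory dates or sponsors
   -> duplicate;
5. otherwise -> non-duplicate (doubt resolves to non-duplicate).

The engine approximates, not replicates, a human rater; it is mainly
exercised against synthetic corpora with planted truth.  Human (or oracle)
ratings travel as a three-column TSV: ``id_a  id_b  verdict``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .corpus import RegistryRecord
from .linkage import tokenize_secondary_ids
from .similarity import normalize_text, tokenize

__all__ = [
    "Judgment",
    "RuleConfig",
    "is_grant_number",
    "contradictory_titles",
    "adjudicate_pair",
    "read_ratings",
    "write_ratings",
    "VERDICTS",
]

VERDICTS = ("duplicate", "non_duplicate", "unknown")

#: US federal grant numbers in the NIH shape: optional application-type
#: digit, activity code (letter + 2 digits), institute code (2 letters),
#: 5-6 digit serial, optional suffix — e.g. "R01HL123456", "5U01AI12345-02".
DEFAULT_GRANT_PATTERNS = (
    r"^\d?[A-Za-z]\d{2}[A-Za-z]{2}\d{5,6}(-[A-Za-z0-9]+)?$",
)

DEFAULT_ANTONYM_PAIRS = (
    ("fed", "fasting"),
    ("fed", "fasted"),
    ("single", "multiple"),
    ("open", "blind"),
    ("adults", "children"),
)

#: Phrases that mark a separately registered follow-on protocol; present in
#: exactly one title of a near-identical pair they indicate a new trial.
DEFAULT_FLAG_PHRASES = ("extension", "follow up", "rollover")


@dataclass
class RuleConfig:
    """Tunable knobs of the rule engine."""

    antonym_pairs: Sequence[tuple[str, str]] = DEFAULT_ANTONYM_PAIRS
    flag_phrases: Sequence[str] = DEFAULT_FLAG_PHRASES
    grant_patterns: Sequence[str] = DEFAULT_GRANT_PATTERNS
    min_strong_id_len: int = 5        # shared IDs must be longer than this
    field_similarity_floor: float = 0.75
    date_window_days: int = 365
    _grant_res: list[re.Pattern] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.min_strong_id_len < 1:
            raise ValueError("min_strong_id_len must be >= 1")
        self._grant_res = [re.compile(p) for p in self.grant_patterns]


def is_grant_number(token: str, config: RuleConfig | None = None) -> bool:
    """True iff the token matches a configured US federal grant pattern."""
    config = config or RuleConfig()
    token = token.strip()
    if not token:
        return False
    return any(p.match(token) for p in config._grant_res)


def _title_cosine(tokens_a: set[str], tokens_b: set[str]) -> float:
    # unit-weight cosine over token sets: enough for the "near identical"
    # test, which must not depend on a corpus-level index
    if not tokens_a or not tokens_b:
        return 0.0
    shared = len(tokens_a & tokens_b)
    return shared / (len(tokens_a) ** 0.5 * len(tokens_b) ** 0.5)


def contradictory_titles(a: str, b: str, config: RuleConfig | None = None) -> bool:
    """True iff two titles are near-identical apart from a contradictory
    phrase pair (or an extension-study phrase on one side only)."""
    config = config or RuleConfig()
    ta = set(tokenize(normalize_text(a)))
    tb = set(tokenize(normalize_text(b)))
    if ta == tb:
        return False
    if _title_cosine(ta, tb) < config.field_similarity_floor:
        return False
    for p, q in config.antonym_pairs:
        if (p in ta and p not in tb and q in tb and q not in ta) or \
           (q in ta and q not in tb and p in tb and p not in ta):
            return True
    na, nb = normalize_text(a), normalize_text(b)
    for phrase in config.flag_phrases:
        if (phrase in na) != (phrase in nb):
            return True
    return False


@dataclass(frozen=True)
class Judgment:
    verdict: str
    fired_rule: str
    rationale: str


def _id_tokens(rec: RegistryRecord) -> set[str]:
    return {t.text.strip().casefold()
            for t in tokenize_secondary_ids(rec.secondary_ids)}


def _skeleton(token: str) -> str:
    return "".join("A" if c.isalpha() else "9" if c.isdigit() else c
                   for c in token)


def _norm_sponsors(rec: RegistryRecord) -> set[str]:
    return {" ".join(s.casefold().split()) for s in rec.sponsors if s.strip()}


def adjudicate_pair(
    a: RegistryRecord,
    b: RegistryRecord,
    score_context: Mapping[str, float] | None = None,
    config: RuleConfig | None = None,
) -> Judgment:
    """Apply the duplicate-judgment rules in precedence order.

    ``score_context`` may carry precomputed field similarities (key
    ``"title"``); absent that, an unweighted token cosine of the
    concatenated titles is used for rule 4.  The verdict is symmetric in
    the two records.
    """
    config = config or RuleConfig()

    # 1. contradictory titles
    if contradictory_titles(a.concatenated_title, b.concatenated_title, config):
        return Judgment("non_duplicate", "contradictory_titles",
                        "near-identical titles with contradictory phrases")

    sponsors_shared = bool(_norm_sponsors(a) & _norm_sponsors(b))
    ids_a, ids_b = _id_tokens(a), _id_tokens(b)

    # 2. shared sponsor + shared strong secondary ID
    if sponsors_shared:
        strong = {
            t for t in ids_a & ids_b
            if len(t) > config.min_strong_id_len and not is_grant_number(t, config)
        }
        if strong:
            return Judgment("duplicate", "shared_strong_id",
                            f"shared sponsor and secondary ID {sorted(strong)[0]!r}")

    # 3. shared sponsor + distinct same-format IDs (shared weak tokens such
    # as grant numbers do not block this rule; only the non-shared IDs count)
    if sponsors_shared:
        fmt_a = {_skeleton(t) for t in ids_a - ids_b
                 if len(t) > config.min_strong_id_len
                 and not is_grant_number(t, config)}
        fmt_b = {_skeleton(t) for t in ids_b - ids_a
                 if len(t) > config.min_strong_id_len
                 and not is_grant_number(t, config)}
        if fmt_a & fmt_b:
            return Judgment("non_duplicate", "same_format_distinct_ids",
                            "shared sponsor but different IDs in the same format")

    # 4. overall field similarity without contradictions
    if score_context and "title" in score_context:
        sim = score_context["title"]
    else:
        sim = _title_cosine(
            set(tokenize(normalize_text(a.concatenated_title))),
            set(tokenize(normalize_text(b.concatenated_title))),
        )
    if sim >= config.field_similarity_floor:
        da = a.chosen_variant.date_enrolment or a.chosen_variant.date_registered
        db = b.chosen_variant.date_enrolment or b.chosen_variant.date_registered
        dates_ok = (
            da is None or db is None
            or abs((da - db).days) <= config.date_window_days
        )
        sponsors_ok = (
            sponsors_shared or not _norm_sponsors(a) or not _norm_sponsors(b)
        )
        if dates_ok and sponsors_ok:
            return Judgment("duplicate", "field_similarity",
                            f"title similarity {sim:.2f} with no contradictions")

    # 5. doubt resolves to non-duplicate
    return Judgment("non_duplicate", "default_doubt",
                    "no positive signal; doubt resolves to non-duplicate")


# ---------------------------------------------------------------------------
# Ratings I/O
# ---------------------------------------------------------------------------

def write_ratings(
    judgments: Iterable[tuple[str, str, str]], path
) -> None:
    """Write ``(id_a, id_b, verdict)`` rows as a ratings TSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("id_a", "id_b", "verdict"))
        for id_a, id_b, verdict in judgments:
            if verdict not in VERDICTS:
                raise ValueError(f"invalid verdict {verdict!r}")
            writer.writerow((id_a, id_b, verdict))


def read_ratings(path) -> list[tuple[str, str, str]]:
    """Read a ratings TSV, validating verdict values (with line numbers)."""
    out: list[tuple[str, str, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[:3] != ["id_a", "id_b", "verdict"]:
            raise ValueError("ratings file must start with header id_a/id_b/verdict")
        for i, row in enumerate(reader, start=2):
            if len(row) < 3:
                raise ValueError(f"line {i}: expected 3 columns")
            id_a, id_b, verdict = row[0], row[1], row[2]
            if verdict not in VERDICTS:
                raise ValueError(f"line {i}: invalid verdict {verdict!r}")
            out.append((id_a, id_b, verdict))
    return out
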