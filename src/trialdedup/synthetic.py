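"""Synthetic multi-registry corpora with planted duplicate ground truth.

The generator emulates the *statistical* structure a registry
deduplication analysis relies on, not registry prose: titles drawn from a
Zipf vocabulary plus trial-specific rare tokens (so IDF weighting is
informative and the title field discriminates), per-registry field
dialects of differing verbosity, EUCTR-style member-state variants,
redacted records, filler and grant-number secondary IDs, and near-
duplicate confounders (contradictory-phrase twins and post-hoc extension
studies) that populate the high-similarity non-duplicate region.

A configurable fraction of trials is registered more than once; each such
duplicate cluster is either *known* — its records cross-reference one
another through secondary IDs, so ID linkage alone recovers the cluster —
or *hidden*, carrying no linking IDs at all.  The returned
:class:`TruthLabels` partition is exact and is the oracle against which
the pipeline's estimates are judged.

All randomness flows through one seeded generator; a fixed seed gives a
byte-identical corpus.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

from .corpus import RecordVariant

__all__ = [
    "GeneratorParams",
    "TruthLabels",
    "TruthSummary",
    "ictrp_like",
    "generate_corpus",
    "truth_summary",
]

_REGISTRIES = (
    "ClinicalTrials.gov", "EUCTR", "ISRCTN", "JPRN", "ANZCTR", "DRKS",
)
_EU_STATES = ("AT", "BE", "CZ", "DE", "DK", "ES", "FI", "FR", "GB", "GR",
              "HU", "IE", "IT", "LV", "NL", "PL", "PT", "SE")
_COUNTRIES = ("United States", "Germany", "France", "Japan", "Australia",
              "United Kingdom", "Netherlands", "Canada", "Spain", "Italy",
              "Belgium", "Poland", "Denmark", "Sweden", "New Zealand")
_NONSENSE_IDS = ("Version 1", "Nil known", "N/A", "none", "0001",
                 "Protocol v2.0")
_SPONSOR_SUFFIX = ("Inc", "Ltd", "GmbH", "University", "Foundation")
_GRANT_INSTITUTES = ("HL", "CA", "AI", "MH", "DK")


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic corpus generator.

    ``dup_rate`` is the fraction of trials registered more than once;
    ``known_link_fraction`` the fraction of those duplicate clusters whose
    records are cross-linked by secondary IDs (the rest are hidden).
    ``title_perturbation`` is the per-word deletion/substitution
    probability applied to every registration after a trial's first.
    ``confounder_rate`` plants near-duplicate *non*-duplicates.
    """

    n_trials: int = 20_000
    n_registries: int = 5
    dup_rate: float = 0.09
    known_link_fraction: float = 0.55
    title_perturbation: float = 0.08
    vocab_size: int = 2_000
    zipf_exponent: float = 1.2
    redaction_rate: float = 0.01
    nonsense_id_rate: float = 0.05
    grant_id_rate: float = 0.03
    confounder_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 2 <= self.n_registries <= len(_REGISTRIES):
            raise ValueError(f"n_registries must be in [2, {len(_REGISTRIES)}]")
        for name in ("dup_rate", "known_link_fraction", "title_perturbation",
                     "redaction_rate", "nonsense_id_rate", "grant_id_rate",
                     "confounder_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dup_rate == 0.0 and self.known_link_fraction > 0.0:
            warnings.warn("known_link_fraction > 0 has no effect when "
                          "dup_rate is 0", stacklevel=2)


def ictrp_like(seed: int = 0, **overrides) -> GeneratorParams:
    """The default preset: a corpus echoing the scale and mixture of the
    WHO ICTRP portal snapshot (about 9% of records duplicated, slightly
    over half of the duplicate clusters identifiable from secondary IDs).
    """
    return GeneratorParams(seed=seed, **overrides)


@dataclass(frozen=True)
class TruthSummary:
    trials: int
    records: int
    known_pairs: int
    hidden_pairs: int
    hidden_fraction: float


@dataclass
class TruthLabels:
    """Exact ground truth for a generated corpus.

    ``record_to_trial`` maps record stems to trial ids; multi-record
    trials carry a known/hidden flag.  A record pair is a true duplicate
    iff both records map to the same trial.
    """

    record_to_trial: dict[str, str]
    cluster_known: dict[str, bool]
    confounder_pairs: list[tuple[str, str]] = field(default_factory=list)

    def is_duplicate(self, id_a: str, id_b: str) -> bool:
        return (self.record_to_trial.get(id_a) is not None
                and self.record_to_trial.get(id_a) == self.record_to_trial.get(id_b))

    def _trial_members(self) -> dict[str, list[str]]:
        members: dict[str, list[str]] = {}
        for rec, trial in self.record_to_trial.items():
            members.setdefault(trial, []).append(rec)
        return members

    def duplicate_pairs(self) -> dict[tuple[str, str], bool]:
        """All true duplicate pairs, mapped to their known flag."""
        out: dict[tuple[str, str], bool] = {}
        for trial, members in self._trial_members().items():
            if len(members) < 2:
                continue
            known = self.cluster_known.get(trial, False)
            for a, b in combinations(sorted(members), 2):
                out[(a, b)] = known
        return out

    def known_clusters(self) -> list[frozenset[str]]:
        return [frozenset(m) for t, m in self._trial_members().items()
                if len(m) >= 2 and self.cluster_known.get(t, False)]

    def rater(self) -> Callable[[str, str], str]:
        """An oracle rater: verdicts straight from the truth partition."""
        def rate(id_a: str, id_b: str) -> str:
            return "duplicate" if self.is_duplicate(id_a, id_b) else "non_duplicate"
        return rate


def truth_summary(truth: TruthLabels) -> TruthSummary:
    """Exact counts from the truth partition.

    ``hidden_fraction`` = hidden pairs / (known + hidden pairs); zero when
    there are no duplicate pairs at all.
    """
    pairs = truth.duplicate_pairs()
    known = sum(1 for flag in pairs.values() if flag)
    hidden = len(pairs) - known
    total = known + hidden
    return TruthSummary(
        trials=len(set(truth.record_to_trial.values())),
        records=len(truth.record_to_trial),
        known_pairs=known,
        hidden_pairs=hidden,
        hidden_fraction=hidden / total if total else 0.0,
    )


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------

_LETTERS = np.array(list(string.ascii_lowercase))


def _make_vocab(rng: np.random.Generator, size: int) -> list[str]:
    lengths = rng.integers(4, 10, size=size)
    words: list[str] = []
    seen: set[str] = set()
    for i, ln in enumerate(lengths):
        w = "".join(rng.choice(_LETTERS, size=ln))
        if w in seen:
            w = f"{w}{i}"
        seen.add(w)
        words.append(w)
    return words


def _zipf_probs(size: int, s: float) -> np.ndarray:
    p = 1.0 / np.arange(1, size + 1, dtype=float) ** s
    return p / p.sum()


@dataclass
class _TrialCore:
    trial_id: str
    title: list[str]
    condition: list[str]
    intervention: list[str]
    outcome: list[str]
    inclusion: list[str]
    sponsor: str
    protocol_id: str
    base_date: date
    countries: list[str]


class _IdMint:
    """Deterministic unique registry ids."""

    def __init__(self, rng: np.random.Generator):
        self.counters = {name: int(rng.integers(10_000, 50_000))
                         for name in _REGISTRIES}
        self.rng = rng

    def next_id(self, registry: str) -> str:
        self.counters[registry] += 1
        k = self.counters[registry]
        if registry == "ClinicalTrials.gov":
            return f"NCT{k:08d}"
        if registry == "EUCTR":
            year = 2004 + k % 11
            return f"EUCTR{year}-{k:06d}-{k % 100:02d}"
        if registry == "ISRCTN":
            return f"ISRCTN{k:08d}"
        if registry == "JPRN":
            return f"JPRN-UMIN{k:09d}"
        if registry == "ANZCTR":
            return f"ACTRN{k:014d}"
        return f"DRKS{k:08d}"


class _WordPool:
    """Batched Zipf word sampler (one large draw amortizes the CDF walk)."""

    def __init__(self, rng: np.random.Generator, vocab: list[str],
                 probs: np.ndarray, batch: int = 100_000):
        self.rng, self.vocab, self.probs, self.batch = rng, vocab, probs, batch
        self._buf = np.empty(0, dtype=np.int64)
        self._pos = 0

    def draw(self, k: int) -> list[str]:
        if self._pos + k > len(self._buf):
            size = max(self.batch, k)
            self._buf = self.rng.choice(len(self.vocab), size=size, p=self.probs)
            self._pos = 0
        out = [self.vocab[i] for i in self._buf[self._pos:self._pos + k]]
        self._pos += k
        return out


def _sample_words(rng, pool: "_WordPool", lo, hi) -> list[str]:
    k = int(rng.integers(lo, hi + 1))
    return pool.draw(k)


def _perturb(rng, words: Sequence[str], p: float, vocab: list[str]) -> list[str]:
    if p <= 0.0 or not words:
        return list(words)
    u = rng.random(len(words))
    out: list[str] = []
    for w, r in zip(words, u):
        if r < p / 2.0:
            continue  # deletion
        if r < p:
            out.append(vocab[int(rng.integers(len(vocab)))])  # substitution
        else:
            out.append(w)
    return out


def generate_corpus(
    params: GeneratorParams,
) -> tuple[list[RecordVariant], TruthLabels]:
    """Generate a corpus of record variants plus exact truth labels.

    Reproducible: a fixed ``params.seed`` yields a byte-identical corpus.
    """
    rng = np.random.default_rng(params.seed)
    vocab = _make_vocab(rng, params.vocab_size)
    probs = _zipf_probs(params.vocab_size, params.zipf_exponent)
    pool = _WordPool(rng, vocab, probs)
    mint = _IdMint(rng)
    registries = list(_REGISTRIES[: params.n_registries])

    # sponsor pool with Zipf-ish usage and per-sponsor protocol prefixes
    n_sponsors = max(5, params.n_trials // 40)
    sponsor_names = [
        f"{vocab[int(rng.integers(len(vocab)))].capitalize()} "
        f"{_SPONSOR_SUFFIX[int(rng.integers(len(_SPONSOR_SUFFIX)))]}"
        for _ in range(n_sponsors)
    ]
    sponsor_prefix = [
        "".join(rng.choice(_LETTERS, size=3)).upper() for _ in range(n_sponsors)
    ]
    sponsor_probs = _zipf_probs(n_sponsors, 1.05)

    grant_pool_size = max(3, int(params.grant_id_rate * params.n_trials / 4) or 3)
    grant_pool = [
        f"R01{_GRANT_INSTITUTES[int(rng.integers(len(_GRANT_INSTITUTES)))]}"
        f"{int(rng.integers(100000, 999999)):06d}"
        for _ in range(grant_pool_size)
    ]

    protocol_serial = int(rng.integers(1000, 5000))

    def make_core(idx: int, trial_id: str) -> _TrialCore:
        nonlocal protocol_serial
        protocol_serial += 1
        si = int(rng.choice(n_sponsors, p=sponsor_probs))
        drug = "".join(rng.choice(_LETTERS, size=4)) + str(idx)
        proto_word = "".join(rng.choice(_LETTERS, size=5)) + str(idx)
        title = _sample_words(rng, pool, 6, 12) + [drug, proto_word]
        return _TrialCore(
            trial_id=trial_id,
            title=title,
            condition=_sample_words(rng, pool, 2, 4),
            intervention=_sample_words(rng, pool, 2, 4) + [drug],
            outcome=_sample_words(rng, pool, 3, 8),
            inclusion=_sample_words(rng, pool, 5, 12),
            sponsor=sponsor_names[si],
            protocol_id=f"{sponsor_prefix[si]}-{protocol_serial:04d}",
            base_date=date(2005, 1, 1) + timedelta(int(rng.integers(0, 3650))),
            countries=[_COUNTRIES[i] for i in
                       rng.choice(len(_COUNTRIES),
                                  size=int(rng.integers(1, 4)), replace=False)],
        )

    cores = [make_core(i, f"T{i:06d}") for i in range(params.n_trials)]

    # duplicate-cluster plan
    n_dup = int(round(params.dup_rate * params.n_trials))
    dup_idx = rng.choice(params.n_trials, size=n_dup, replace=False)
    sizes = (2 + (rng.random(n_dup) < 0.11).astype(int)
             + (rng.random(n_dup) < 0.015).astype(int))
    sizes = np.minimum(sizes, params.n_registries)
    known_flags = rng.random(n_dup) < params.known_link_fraction
    n_records_of = np.ones(params.n_trials, dtype=int)
    n_records_of[dup_idx] = sizes
    cluster_known: dict[str, bool] = {
        cores[i].trial_id: bool(k) for i, k in zip(dup_idx, known_flags)
    }

    # confounders: near-duplicate twins that are genuinely different trials
    n_conf = int(round(params.confounder_rate * params.n_trials))
    conf_base = rng.choice(params.n_trials, size=n_conf, replace=False)
    conf_cores: list[_TrialCore] = []
    conf_of_base: list[tuple[int, int]] = []  # (base trial idx, conf core idx)
    for j, bi in enumerate(conf_base):
        base = cores[bi]
        protocol_serial += 1
        si = sponsor_names.index(base.sponsor)
        if rng.random() < 0.5:
            # contradictory-phrase twin: base under fed, twin under fasting
            base.title = base.title + ["under", "fed", "conditions"]
            twin_title = base.title[:-3] + ["under", "fasting", "conditions"]
            twin_date = base.base_date + timedelta(int(rng.integers(0, 180)))
        else:
            # post-hoc extension study: same population, new protocol
            twin_title = base.title + ["extension", "study"]
            twin_date = base.base_date + timedelta(int(rng.integers(400, 1100)))
        conf_cores.append(replace(
            base,
            trial_id=f"C{j:06d}",
            title=twin_title,
            protocol_id=f"{sponsor_prefix[si]}-{protocol_serial:04d}",
            base_date=twin_date,
        ))
        conf_of_base.append((int(bi), j))

    # record emission
    variants: list[RecordVariant] = []
    record_to_trial: dict[str, str] = {}
    first_record_ids: dict[str, tuple[str, str]] = {}  # trial -> (stem, registry)
    confounder_pairs: list[tuple[str, str]] = []

    def emit_record(core: _TrialCore, registry: str, ordinal: int,
                    linked: bool) -> str:
        """Emit one record (with variants for EUCTR); returns the stem."""
        pert = params.title_perturbation if ordinal > 0 else 0.0
        title = _perturb(rng, core.title, pert, vocab)
        condition = _perturb(rng, core.condition, pert, vocab)
        intervention = _perturb(rng, core.intervention, pert, vocab)
        outcome = _perturb(rng, core.outcome, pert, vocab)
        inclusion = _perturb(rng, core.inclusion, pert, vocab)

        # registry dialects: verbosity differs systematically by registry
        if registry == "ClinicalTrials.gov":
            outcome = outcome + _sample_words(rng, pool, 3, 5)
        elif registry == "EUCTR":
            intervention = ["product"] + intervention + ["dose"]
        elif registry == "JPRN":
            inclusion = inclusion[:5]

        stem = mint.next_id(registry)
        secondary: list[str] = [core.protocol_id]
        if linked and ordinal > 0:
            ref_stem, ref_registry = first_record_ids[core.trial_id]
            if ref_registry == "EUCTR":
                # references to EUCTR records often drop the EUCTR prefix
                if rng.random() < 0.5:
                    secondary.append(ref_stem)
                else:
                    secondary.append(ref_stem[5:])  # bare EudraCT number
            else:
                secondary.append(ref_stem)
        if rng.random() < params.nonsense_id_rate:
            secondary.append(_NONSENSE_IDS[int(rng.integers(len(_NONSENSE_IDS)))])
        if rng.random() < params.grant_id_rate:
            secondary.append(grant_pool[int(rng.integers(len(grant_pool)))])

        redacted = rng.random() < params.redaction_rate
        public = " ".join(title)
        scientific = ""
        acronym = ""
        if registry == "ClinicalTrials.gov" and rng.random() < 0.2:
            acronym = core.title[-2].upper()
        if redacted:
            public = ("N/A" if registry == "EUCTR" else
                      "[Trial of device that is not approved or cleared "
                      "by the U.S. FDA]")
            scientific = ""
            acronym = ""

        d0 = core.base_date + timedelta(int(rng.integers(0, 90)))
        common = dict(
            registry=registry,
            public_title=public,
            scientific_title=scientific,
            acronym=acronym,
            secondary_ids=secondary,
            conditions=[" ".join(condition)],
            interventions=[" ".join(intervention)],
            outcomes=[" ".join(outcome)],
            inclusion_criteria=" ".join(inclusion),
            sponsors=[core.sponsor],
            date_enrolment=None,
            countries=core.countries,
        )
        if registry == "EUCTR":
            n_var = int(rng.integers(1, 4))
            states = rng.choice(len(_EU_STATES), size=n_var, replace=False)
            offsets = [0] + [int(rng.integers(1, 300)) for _ in range(n_var - 1)]
            for cc_i, off in zip(states, offsets):
                variants.append(RecordVariant(
                    registry_id=f"{stem}-{_EU_STATES[cc_i]}",
                    date_registered=d0 + timedelta(off),
                    **common,
                ))
        else:
            variants.append(RecordVariant(
                registry_id=stem, date_registered=d0, **common))
        record_to_trial[stem] = core.trial_id
        if ordinal == 0:
            first_record_ids[core.trial_id] = (stem, registry)
        return stem

    conf_record_of: dict[int, str] = {}
    base_record_of: dict[int, str] = {}
    for i, core in enumerate(cores):
        k = int(n_records_of[i])
        regs = [registries[j] for j in
                rng.choice(len(registries), size=k, replace=False)]
        linked = cluster_known.get(core.trial_id, False)
        for ordinal, registry in enumerate(regs):
            stem = emit_record(core, registry, ordinal, linked)
            if ordinal == 0:
                base_record_of[i] = stem
    for j, core in enumerate(conf_cores):
        registry = registries[int(rng.integers(len(registries)))]
        stem = emit_record(core, registry, 0, False)
        conf_record_of[j] = stem
    for bi, j in conf_of_base:
        confounder_pairs.append(tuple(sorted(
            (base_record_of[bi], conf_record_of[j]))))

    truth = TruthLabels(
        record_to_trial=record_to_trial,
        cluster_known=cluster_known,
        confounder_pairs=confounder_pairs,
    )
    return variants, truth
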