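from __future__ import annotations

from datetime import date

import pytest
from hypothesis import settings

from trialdedup.corpus import RecordVariant, RegistryRecord, consolidate_variants
from trialdedup.synthetic import generate_corpus, ictrp_like

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


def make_record(
    record_id: str,
    *,
    registry: str = "ClinicalTrials.gov",
    public_title: str = "",
    scientific_title: str = "",
    acronym: str = "",
    secondary_ids: tuple[str, ...] = (),
    conditions: tuple[str, ...] = (),
    interventions: tuple[str, ...] = (),
    outcomes: tuple[str, ...] = (),
    inclusion_criteria: str = "",
    sponsors: tuple[str, ...] = (),
    date_registered: date | None = None,
    date_enrolment: date | None = None,
) -> RegistryRecord:
    """One-variant record for hand-built fixtures."""
    variant = RecordVariant(
        registry_id=record_id,
        registry=registry,
        public_title=public_title,
        scientific_title=scientific_title,
        acronym=acronym,
        secondary_ids=list(secondary_ids),
        conditions=list(conditions),
        interventions=list(interventions),
        outcomes=list(outcomes),
        inclusion_criteria=inclusion_criteria,
        sponsors=list(sponsors),
        date_registered=date_registered,
        date_enrolment=date_enrolment,
    )
    (record,) = consolidate_variants([variant])
    return record


@pytest.fixture(scope="session")
def small_corpus():
    """A 400-trial synthetic corpus with truth labels (shared, read-only)."""
    params = ictrp_like(seed=123, n_trials=400, vocab_size=500)
    variants, truth = generate_corpus(params)
    records = consolidate_variants(variants)
    return variants, records, truth
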