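# Methods

## Overview

`trialdedup` estimates how many duplicate registrations in a
multi-registry clinical-trial corpus are *hidden* — not identifiable from
secondary-ID links alone.  The design is a two-stage sieve: a cheap,
deliberately unspecific text-similarity score reduces billions of record
pairs to a tractable candidate set, and a design-based estimator converts
rated random samples of candidates into an estimate of the hidden
population with exact binomial uncertainty.  The similarity score does not
need to be a good duplicate classifier; it only needs to concentrate
duplicates at high scores so that sampling is efficient, with the
known-duplicate score distribution serving to correct for the duplicates
the sieve misses.

## Record model and consolidation

A *trial* may have several *records* (one per registration), and an EUCTR
record has one published *variant* per EU member state.  Consolidation
maps every variant ID of the shape `EUCTR<dddd-dddddd-dd>-<CC>` (CC a
two-letter member-state code) to its stem; all other registry IDs are
their own stems.  For multi-variant records the earliest-registered
variant represents the record, with ties broken lexicographically by
member-state suffix and missing dates sorting last — the choice of
tie-break is arbitrary but must be deterministic, since downstream scores
depend on the chosen variant's text.  All variants' secondary IDs remain
visible to linkage regardless of which variant is chosen.  A record whose
public title is a redaction placeholder (`N/A` in EUCTR, the bracketed
unapproved-device marker in ClinicalTrials.gov; the marker list is
configurable) vectorizes to the empty vector and therefore scores zero
against everything.

## Known-duplicate grouping

Secondary-ID values are split into tokens at whitespace and `, ; .` —
because `.` is a separator, identifiers with internal dots are split; we
accept this as the cost of a simple, reproducible rule.  A token matches a
record when it equals (case-insensitively, after trimming) the record's
registry ID, any of its variant IDs, or — for EUCTR — the stem or the
bare EudraCT number (`dddd-dddddd-dd`), since references written before
the EUCTR web register existed often lack the prefix.  Tokens shorter
than 4 characters, or on a small stop list of filler values
("nil", "none", "known", "version", ...), never produce edges; this is our
operationalization of discarding "clearly nonsensical" IDs, which has no
canonical definition.  Groups are connected components over match edges
(networkx); every record in a group is a known duplicate of every other.
US federal grant numbers are never used for grouping: one grant commonly
funds many distinct trials, so grant matches are handled (and excluded) in
adjudication instead.  Two corroboration utilities — grouping by shared
WHO UTN (`U1111-dddd-dddd`) and matching an external sponsor identifier
list restricted to sponsor-filtered records — mirror strategies for
mining additional value from the secondary-ID field; they produce edge
lists but are not part of the default grouping.

## Similarity scoring

Text is case-folded, NFKD-decomposed with combining marks removed, and
reduced to Latin letters, digits, punctuation and single spaces;
characters with no Latin transliteration become spaces, and a record whose
normalized title is empty behaves like a redacted record.  Tokens are
maximal runs of `[a-z0-9]`.  Five fields are scored: the *concatenated
title* (public title + scientific title + acronym, pooled because
registries use them inconsistently), condition, intervention, outcome and
inclusion criteria, multi-valued fields joined by spaces.

Term weights are inverse document frequency, `w(t) = ln(N / df(t))`,
computed per field with binary per-record document frequencies; stop words
(a fixed English list shipped in `trialdedup.stopwords`) and
punctuation-only tokens get weight exactly 0.  We fix `ln(N/df)` without
smoothing for reproducibility; any monotone IDF variant would serve.
Presence is binary — repeating a word within a field does not increase
its weight — but the same word in two fields is two distinct features.
Similarity is the cosine of the two weighted vectors, 0 when either
vector is empty.  The title field is the operational choice for the
pipeline (it discriminates duplicates from arbitrary pairs best); the
combined all-field score is available through `vectorize(..., fields=...)`.

## The lossless thresholded join

The contract of `all_pairs_above` is exactness: the returned set equals
exhaustive enumeration at the threshold, with pairs scoring precisely at
the threshold included.  Two provable pruning devices make it cheap:

* cosine over non-negative weights is positive only if the vectors share
  a non-zero-weight term, so candidates come from an inverted index;
* within each L2-normalized vector, terms are sorted by descending weight
  and the lowest-weight *tail* is grown while its norm stays below the
  threshold (minus a 1e-9 safety margin for float rounding).  If two
  vectors share no term outside their tails, the dot product is bounded by
  `||tail|| · 1 < threshold`, so only pairs sharing a *head* term need
  scoring.  High-frequency terms have low IDF weight, land in tails, and
  thus never explode the candidate set.

Candidate structure is computed as a sparse pattern product; exact scores
are then evaluated for candidates only.  A non-positive threshold is
rejected (it would enumerate all n(n−1)/2 pairs).

## Hidden-duplicate estimation

Scored pairs are split into known (same linkage group) and candidates,
and bucketed into ranges `lo < s ≤ hi` (default `(0.5,0.6] ... (0.9,1.0]`,
matching the reporting convention of the reference analysis).  From each
range's candidate pool a uniform without-replacement sample is rated; the
proportion rated duplicate, with its Clopper–Pearson interval, scales to
the pool size and is compared with the range's known pairs (formulas in
the README).  Interval endpoints are mapped through the same formulas,
which is valid because the hidden-percentage mapping is strictly
increasing in the proportion.

The overall extrapolation divides the summed unknown-pair estimates by the
*coverage* — the fraction of all known-duplicate pairs whose score falls
in the examined ranges — under the stated assumption that a duplicate's
probability of being hidden does not depend on its similarity score.  The
overall interval sums per-range interval endpoints before mapping; this is
conservative (it ignores that strata are independent), which the
end-to-end recovery test bears out.  The adjusted unique-trial count
subtracts one trial per estimated hidden pair, ignoring the possibility
that two hidden pairs merge three records into one trial; at observed
duplication rates the approximation is at the rounding level of the
reported thousands.  `required_sample_size` returns the smallest n whose
interval, evaluated at the expected success count `round(p·n)` (half away
from zero), lies within the target bounds — the rounding convention for
the expected count is ours, so order-of-magnitude agreement is all that
is claimed for planning numbers.  Reported percentages are rounded half
away from zero at presentation time only.

Clopper–Pearson bounds come from beta-distribution quantiles
(`scipy.stats.beta.ppf`), with the lower bound exactly 0 at x = 0 and the
upper exactly 1 at x = n; the test suite validates them against an
independent bisection on exact binomial tail sums to 1e-9.

## Adjudication rules

The manual duplicate-judgment criteria are encoded as an ordered,
deterministic rule engine (first firing rule wins); precedence and
defaults are documented in `trialdedup.adjudication`.  Points that
required operationalization: "two identical secondary IDs" is read as at
least one shared secondary-ID token longer than 5 characters (matching
the linkage logic); "same format" is equal length plus equal
letter/digit/punctuation skeleton; US grant numbers are recognized by an
NIH-shaped pattern (optional type digit, activity code, institute code,
5–6 digit serial); date contradiction is start dates more than 365 days
apart when both are present; and separately registered extension studies
are flagged through extension phrases appearing on exactly one side of a
near-identical title pair.  The engine is an explicit approximation of a
human rater — difficult cases in the reference analysis were resolved by
discussion, for which no machine-reproducible criterion exists — and it
is validated only against synthetic truth, where it agrees with planted
labels on >90% of informative pairs at default noise.

## Synthetic corpora

The generator plants a duplicate-cluster structure and emits exact truth
labels.  Defaults follow the corpus the analysis is designed for: 9% of
trials registered more than once (`dup_rate=0.09`), 55% of duplicate
clusters ID-linked (`known_link_fraction=0.55`), five registries, ~11% of
clusters of size three or more.  Titles mix a 2,000-word Zipf vocabulary
(exponent 1.2) with two trial-specific rare tokens, so IDF weighting is
informative and the title field discriminates — the same mechanism that
makes titles discriminating in real registries.  Per-registry dialects
vary verbosity (richer outcomes in the ClinicalTrials.gov analogue,
structured intervention extras in the EUCTR analogue, truncated inclusion
criteria in the JPRN analogue); EUCTR records get 1–3 member-state
variants with jittered registration dates.  Registrations after a trial's
first perturb each word with probability 0.08 (half deletions, half
substitutions) — enough to spread duplicate scores below 1 without
breaking separation.  Records also receive filler secondary IDs
("Version 1", "Nil known", ...; rate 0.05), shared grant numbers (rate
0.03), redacted titles (rate 0.01), and 1% of trials spawn a
near-duplicate *non*-duplicate confounder: a contradictory-phrase twin
("fed" / "fasting") or a post-hoc extension study sharing sponsor,
vocabulary and drug code.  Known clusters are linked by construction
(each later record cites the first record's ID, EUCTR references dropping
the prefix half the time), hidden clusters carry no linking IDs, and
filler/grant/protocol IDs cannot collide with registry-ID formats — so
the truth partition is exactly recoverable/irrecoverable as labeled.

What the generator does **not** emulate: real registry prose and
vocabulary overlap between related-but-distinct trials, non-English EUCTR
variants, inconsistent date formats, ICTRP false-positive groupings, and
sponsor-behaviour confounding in which well-coordinated sponsors both
title consistently and link their records (the score-independence
assumption is true by construction here).  Passing the end-to-end tests
therefore shows the pipeline and estimator are correct under the stated
assumptions — not that the assumptions hold for any particular real
snapshot.

## Problem sizes in the test suite

The lossless-join contract is checked against exhaustive enumeration on
100 random corpora of up to ~1,000 records at thresholds 0.3/0.5/0.7;
parameter recovery runs 200 end-to-end replicates at 5,000 trials with
planted hidden fractions 0.2/0.45/0.6, requiring ≥90% interval coverage
of the realized truth; interval calibration uses 10,000 simulated
binomial draws at n=100, p=0.13.  These sizes give stable pass/fail
behaviour at sub-percent Monte-Carlo noise while keeping the whole suite
in a few minutes on one core.

## Known limitations

* The estimator is design-based only; no capture–recapture or
  model-based heterogeneity corrections.
* No fuzzy ID matching, no stemming, no learned similarity; losslessness
  and transparency are preferred over recall of the sieve.
* Snapshot-level figures (record counts, known-pair counts, pair counts
  at ≥0.5, known-duplicate score quantiles) depend on the dataset and are
  exposed as `pipeline.observational_summary` for use with an archived
  export rather than asserted as tests.
* The adjudication engine is a stand-in for human judgment, suitable for
  synthetic-truth experiments and first-pass triage, not for definitive
  rating of real record pairs.
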