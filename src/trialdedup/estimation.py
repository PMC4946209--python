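"""Design-based estimation of hidden duplicates from rated samples.

Candidate pairs (highly similar, not ID-linked) are stratified by title
similarity score range.  From each range a uniform without-replacement
sample is rated duplicate / non-duplicate; the binomial proportion ``p``
of duplicates, with its exact Clopper-Pearson confidence interval, scales
to the range's candidate pool ``N`` to give the estimated number of hidden
duplicate pairs ``p * N``.  Comparing that with the known-duplicate pair
count ``K`` in the range gives the percentage of duplicates that remain
hidden, ``100 * pN / (K + pN)`` — a strictly increasing function of ``p``,
so the interval endpoints map through it exactly.  Summing ranges and
dividing by the fraction of known-duplicate pairs the examined ranges
cover (assuming a duplicate's chance of being hidden does not depend on
its score) extrapolates to the overall hidden percentage and an adjusted
unique-trial count.

The module exposes the primitives directly and wraps the whole estimator
as a model/results pair: :class:`HiddenDuplicateModel` holds the per-range
counts, ``fit()`` returns :class:`HiddenDuplicateResults` with estimates,
intervals and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta

from .pairs import ScoredPair, ScoreRange

__all__ = [
    "clopper_pearson",
    "sample_candidates",
    "estimate_range",
    "extrapolate_overall",
    "required_sample_size",
    "round_half_away",
    "RangeSample",
    "RangeEstimate",
    "OverallEstimate",
    "HiddenDuplicateModel",
    "HiddenDuplicateResults",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (as percentages
    are conventionally reported)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (conservative) binomial confidence interval for x successes in
    n trials.

    Computed from beta-distribution quantiles; the lower bound is exactly 0
    when ``x == 0`` and the upper bound exactly 1 when ``x == n``.
    """
    if not 0 <= x <= n or n <= 0:
        raise ValueError(f"require 0 <= x <= n with n > 0, got x={x}, n={n}")
    if not 0.0 < conf < 1.0:
        raise ValueError("conf must be in (0, 1)")
    alpha = 1.0 - conf
    lo = 0.0 if x == 0 else float(beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


@dataclass
class RangeSample:
    """A without-replacement sample of candidate pairs from one score range."""

    range: ScoreRange
    pairs: list[ScoredPair]
    seed: int
    x: int | None = None  # number judged duplicate, once rated

    @property
    def n(self) -> int:
        return len(self.pairs)


def sample_candidates(
    candidates: Sequence[ScoredPair],
    score_range: ScoreRange,
    n: int,
    seed: int,
) -> RangeSample:
    """Uniform without-replacement sample of candidate pairs in a range.

    Reproducible under a fixed seed; ``n`` may not exceed the number of
    candidates whose score falls in the range.
    """
    pool = [p for p in candidates if score_range.contains(p.score)]
    if n > len(pool):
        raise ValueError(
            f"sample size {n} exceeds candidate pool {len(pool)} in {score_range}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return RangeSample(range=score_range, pairs=[pool[i] for i in sorted(idx)],
                       seed=seed)


@dataclass
class RangeEstimate:
    """Hidden-duplicate estimate for one score range."""

    range: ScoreRange | None
    x: int
    n: int
    p_hat: float
    ci: tuple[float, float]
    N_candidates: int
    K_known: int
    unknown_est: float
    unknown_ci: tuple[float, float]
    pct_hidden: float
    pct_ci: tuple[float, float]


def _pct_hidden(unknown: float, known: float) -> float:
    return 100.0 * unknown / (known + unknown)


def estimate_range(
    x: int,
    n: int,
    N_candidates: int,
    K_known: int,
    conf: float = 0.95,
    score_range: ScoreRange | None = None,
) -> RangeEstimate:
    """Point estimate and exact interval for one range.

    ``unknown_est = (x/n) * N_candidates`` and
    ``pct_hidden = 100 * unknown_est / (K_known + unknown_est)``; the
    confidence bounds for the proportion map through the same formulas
    (valid because the mapping is strictly increasing in the proportion).
    Percentages are kept unrounded; round only when reporting.
    """
    if N_candidates <= 0:
        raise ValueError("N_candidates must be positive")
    lo, hi = clopper_pearson(x, n, conf)
    p_hat = x / n
    unknown = p_hat * N_candidates
    if K_known + unknown == 0:
        raise ValueError("pct_hidden undefined: no known pairs and x = 0")
    unknown_lo, unknown_hi = lo * N_candidates, hi * N_candidates
    return RangeEstimate(
        range=score_range,
        x=x,
        n=n,
        p_hat=p_hat,
        ci=(lo, hi),
        N_candidates=N_candidates,
        K_known=K_known,
        unknown_est=unknown,
        unknown_ci=(unknown_lo, unknown_hi),
        pct_hidden=_pct_hidden(unknown, K_known),
        pct_ci=(_pct_hidden(unknown_lo, K_known), _pct_hidden(unknown_hi, K_known)),
    )


@dataclass
class OverallEstimate:
    """Extrapolation of the per-range estimates to all duplicates.

    Valid under the assumption that the probability of a duplicate being
    hidden does not depend on its similarity score; ``coverage`` is the
    fraction of known-duplicate pairs that fall inside the examined ranges.
    The interval sums the per-range interval endpoints, which is
    conservative (it ignores independence between strata).
    """

    coverage: float
    total_known_pairs: int
    unknown_total_est: float
    unknown_total_ci: tuple[float, float]
    pct_hidden_overall: float
    pct_ci: tuple[float, float]
    unique_trials_adjusted: float | None = None


def extrapolate_overall(
    range_estimates: Sequence[RangeEstimate],
    coverage: float,
    total_known_pairs: int,
    n_unique_trials: int | None = None,
) -> OverallEstimate:
    """Combine per-range estimates into the overall hidden percentage.

    ``unknown_total = sum(unknown_est) / coverage``;
    ``pct = 100 * unknown_total / (total_known_pairs + unknown_total)``.
    When ``n_unique_trials`` is given, the adjusted unique-trial count
    subtracts one trial per estimated hidden pair (an approximation that
    ignores hidden triples).
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    unknown = sum(e.unknown_est for e in range_estimates) / coverage
    lo = sum(e.unknown_ci[0] for e in range_estimates) / coverage
    hi = sum(e.unknown_ci[1] for e in range_estimates) / coverage
    return OverallEstimate(
        coverage=coverage,
        total_known_pairs=total_known_pairs,
        unknown_total_est=unknown,
        unknown_total_ci=(lo, hi),
        pct_hidden_overall=_pct_hidden(unknown, total_known_pairs),
        pct_ci=(_pct_hidden(lo, total_known_pairs),
                _pct_hidden(hi, total_known_pairs)),
        unique_trials_adjusted=(
            None if n_unique_trials is None else n_unique_trials - unknown),
    )


def required_sample_size(
    p_expected: float,
    lo_target: float,
    hi_target: float,
    conf: float = 0.95,
    max_n: int = 100_000,
) -> int:
    """Smallest sample size whose Clopper-Pearson interval, evaluated at the
    expected success count ``round(p_expected * n)``, lies within
    ``[lo_target, hi_target]``.
    """
    if not lo_target < p_expected < hi_target:
        raise ValueError("require lo_target < p_expected < hi_target")
    for n in range(1, max_n + 1):
        x = round_half_away(p_expected * n)
        if not 0 <= x <= n:
            continue
        lo, hi = clopper_pearson(x, n, conf)
        if lo >= lo_target and hi <= hi_target:
            return n
    raise ValueError("targets unattainable within max_n samples")


# ---------------------------------------------------------------------------
# Model / Results wrapper
# ---------------------------------------------------------------------------

class HiddenDuplicateModel:
    """Stratified hidden-duplicate estimator over per-range rated samples.

    Parameters
    ----------
    range_data
        DataFrame with one row per examined score range and columns
        ``lo, hi, x, n, n_candidates, k_known``: the sample outcome
        (``x`` duplicates among ``n`` rated pairs), the candidate pool
        size, and the known-duplicate pair count of the range.
    total_known_pairs
        Known-duplicate pairs in the whole corpus (all scores).
    n_unique_trials
        Current unique-trial count (groups), used for the adjusted count.
    coverage
        Fraction of known-duplicate pairs inside the examined ranges.
        If ``None``, computed as ``sum(k_known) / total_known_pairs``.
    """

    def __init__(
        self,
        range_data: pd.DataFrame,
        *,
        total_known_pairs: int,
        n_unique_trials: int | None = None,
        coverage: float | None = None,
    ) -> None:
        required = {"lo", "hi", "x", "n", "n_candidates", "k_known"}
        missing = required - set(range_data.columns)
        if missing:
            raise ValueError(f"range_data lacks columns {sorted(missing)}")
        self.range_data = range_data.reset_index(drop=True)
        self.total_known_pairs = int(total_known_pairs)
        self.n_unique_trials = n_unique_trials
        if coverage is None:
            if self.total_known_pairs <= 0:
                raise ValueError(
                    "coverage cannot be derived without known pairs")
            coverage = float(range_data["k_known"].sum()) / self.total_known_pairs
        self.coverage = float(coverage)

    @classmethod
    def from_samples(
        cls,
        samples: Iterable[RangeSample],
        histogram: pd.DataFrame,
        *,
        total_known_pairs: int,
        n_unique_trials: int | None = None,
        coverage: float | None = None,
    ) -> "HiddenDuplicateModel":
        """Build from rated :class:`RangeSample` objects plus the pair
        histogram produced by :func:`trialdedup.pairs.range_histogram`."""
        rows = []
        hist = histogram.set_index(["lo", "hi"])
        for s in samples:
            if s.x is None:
                raise ValueError(f"sample for {s.range} has not been rated")
            h = hist.loc[(s.range.lo, s.range.hi)]
            rows.append({
                "lo": s.range.lo, "hi": s.range.hi, "x": s.x, "n": s.n,
                "n_candidates": int(h["candidate"]), "k_known": int(h["known"]),
            })
        return cls(pd.DataFrame(rows), total_known_pairs=total_known_pairs,
                   n_unique_trials=n_unique_trials, coverage=coverage)

    def fit(self, conf: float = 0.95) -> "HiddenDuplicateResults":
        estimates = []
        for row in self.range_data.itertuples():
            estimates.append(estimate_range(
                x=int(row.x), n=int(row.n),
                N_candidates=int(row.n_candidates), K_known=int(row.k_known),
                conf=conf, score_range=ScoreRange(row.lo, row.hi),
            ))
        overall = extrapolate_overall(
            estimates, self.coverage, self.total_known_pairs,
            self.n_unique_trials)
        return HiddenDuplicateResults(self, estimates, overall, conf)


class HiddenDuplicateResults:
    """Fitted per-range and overall hidden-duplicate estimates."""

    def __init__(
        self,
        model: HiddenDuplicateModel,
        range_estimates: list[RangeEstimate],
        overall: OverallEstimate,
        conf: float,
    ) -> None:
        self.model = model
        self.range_estimates = range_estimates
        self.overall = overall
        self.conf = conf

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.range_estimates:
            rows.append({
                "range": str(e.range),
                "x": e.x, "n": e.n,
                "pct_in_sample": 100.0 * e.p_hat,
                "known": e.K_known,
                "unknown_est": e.unknown_est,
                "pct_hidden": e.pct_hidden,
                "pct_lo": e.pct_ci[0],
                "pct_hi": e.pct_ci[1],
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable table of the per-range and overall estimates,
        percentages rounded to integers (half away from zero)."""
        lines = [
            "Hidden-duplicate estimation "
            f"({100 * self.conf:g}% exact binomial intervals)",
            "",
            f"{'Score range':>14} {'D. in sample':>14} {'D. known':>9} "
            f"{'D. unknown (est.)':>18} {'% hidden':>15}",
        ]
        for e in self.range_estimates:
            pct = round_half_away(e.pct_hidden)
            lo = round_half_away(e.pct_ci[0])
            hi = round_half_away(e.pct_ci[1])
            lines.append(
                f"{str(e.range):>14} "
                f"{f'{e.x} / {e.n} ({100 * e.p_hat:.1f}%)':>14} "
                f"{e.K_known:>9} {round_half_away(e.unknown_est):>18} "
                f"{f'{pct} ({lo}-{hi})':>15}"
            )
        o = self.overall
        lines += [
            "",
            f"Coverage of known duplicate pairs: {100 * o.coverage:.1f}%",
            f"Known duplicate pairs (all scores): {o.total_known_pairs}",
            f"Estimated hidden duplicate pairs:   "
            f"{round_half_away(o.unknown_total_est)} "
            f"({round_half_away(o.unknown_total_ci[0])}-"
            f"{round_half_away(o.unknown_total_ci[1])})",
            f"Percent of duplicates hidden:       "
            f"{round_half_away(o.pct_hidden_overall)}% "
            f"({round_half_away(o.pct_ci[0])}-{round_half_away(o.pct_ci[1])})",
        ]
        if o.unique_trials_adjusted is not None:
            lines.append(
                "Adjusted unique-trial count:        "
                f"{round_half_away(o.unique_trials_adjusted)}")
        return "\n".join(lines)
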