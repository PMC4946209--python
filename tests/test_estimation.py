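"""Exact binomial intervals, per-range estimates, extrapolation, sampling."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from trialdedup.estimation import (HiddenDuplicateModel, OverallEstimate,
                                   clopper_pearson, estimate_range,
                                   extrapolate_overall, required_sample_size,
                                   round_half_away, sample_candidates)
from trialdedup.pairs import ScoredPair, ScoreRange


def cp_bisection_oracle(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Independent Clopper-Pearson oracle: bisection on exact binomial tail
    sums (no beta-quantile shortcut)."""
    alpha = 1.0 - conf

    def upper_tail(p):  # P(X >= x)
        return sum(math.comb(n, k) * p ** k * (1 - p) ** (n - k)
                   for k in range(x, n + 1))

    def lower_tail(p):  # P(X <= x)
        return sum(math.comb(n, k) * p ** k * (1 - p) ** (n - k)
                   for k in range(0, x + 1))

    def bisect(f, target, increasing):
        lo, hi = 0.0, 1.0
        for _ in range(80):
            mid = (lo + hi) / 2
            if (f(mid) < target) == increasing:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lo = 0.0 if x == 0 else bisect(upper_tail, alpha / 2, increasing=True)
    hi = 1.0 if x == n else bisect(lower_tail, alpha / 2, increasing=False)
    return lo, hi


def test_clopper_pearson_boundaries():
    lo, hi = clopper_pearson(0, 10)
    assert lo == 0.0 and 0 < hi < 1
    lo, hi = clopper_pearson(10, 10)
    assert hi == 1.0 and 0 < lo < 1


def test_clopper_pearson_derived_example():
    lo, hi = clopper_pearson(13, 100)
    assert lo == pytest.approx(0.0711, abs=5e-5)
    assert hi == pytest.approx(0.2124, abs=5e-4)


@pytest.mark.parametrize("x,n", [(0, 7), (3, 7), (7, 7), (13, 100), (89, 209)])
def test_clopper_pearson_agrees_with_tail_sum_bisection(x, n):
    got = clopper_pearson(x, n)
    want = cp_bisection_oracle(x, n)
    assert got[0] == pytest.approx(want[0], abs=1e-9)
    assert got[1] == pytest.approx(want[1], abs=1e-9)


def test_clopper_pearson_invalid_inputs():
    with pytest.raises(ValueError):
        clopper_pearson(5, 4)
    with pytest.raises(ValueError):
        clopper_pearson(1, 10, conf=1.0)


def test_estimate_range_formulas():
    est = estimate_range(x=13, n=100, N_candidates=17_423, K_known=3_489)
    assert est.p_hat == pytest.approx(0.13)
    assert est.unknown_est == pytest.approx(0.13 * 17_423)
    expected_pct = 100 * est.unknown_est / (3_489 + est.unknown_est)
    assert est.pct_hidden == pytest.approx(expected_pct)
    # interval endpoints map monotonically through the same formula
    assert est.pct_ci[0] < est.pct_hidden < est.pct_ci[1]


def test_estimate_range_zero_successes():
    est = estimate_range(x=0, n=50, N_candidates=1000, K_known=20)
    assert est.unknown_est == 0.0
    assert est.pct_hidden == 0.0
    assert est.pct_ci[0] == 0.0


def test_estimate_range_errors():
    with pytest.raises(ValueError):
        estimate_range(x=1, n=10, N_candidates=0, K_known=5)
    with pytest.raises(ValueError):
        estimate_range(x=0, n=10, N_candidates=100, K_known=0)


def test_pct_hidden_strictly_increasing_in_p():
    """The proportion-to-percentage mapping is strictly increasing, which is
    what justifies mapping the interval endpoints directly."""
    N, K = 10_000, 4_000
    pct = [100 * p * N / (K + p * N) for p in np.linspace(0.01, 0.99, 50)]
    assert all(a < b for a, b in zip(pct, pct[1:]))


def test_extrapolate_overall_single_range_consistency():
    est = estimate_range(x=20, n=80, N_candidates=5000, K_known=1500)
    overall = extrapolate_overall([est], coverage=1.0, total_known_pairs=1500)
    assert overall.pct_hidden_overall == pytest.approx(est.pct_hidden)
    assert overall.pct_ci[0] == pytest.approx(est.pct_ci[0])


def test_extrapolate_overall_errors():
    est = estimate_range(x=1, n=10, N_candidates=100, K_known=10)
    with pytest.raises(ValueError):
        extrapolate_overall([est], coverage=0.0, total_known_pairs=10)


def test_required_sample_size_bracketing():
    n = required_sample_size(0.5, 0.3, 0.7)
    x = round_half_away(0.5 * n)
    lo, hi = clopper_pearson(x, n)
    assert 0.3 <= lo and hi <= 0.7
    assert 20 <= n <= 80
    # smallest such n: the scan guarantees every smaller n fails
    x1 = round_half_away(0.5 * (n - 1))
    lo1, hi1 = clopper_pearson(x1, n - 1)
    assert lo1 < 0.3 or hi1 > 0.7


def test_required_sample_size_monotone_in_targets():
    narrow = required_sample_size(0.5, 0.40, 0.60)
    wide = required_sample_size(0.5, 0.30, 0.70)
    assert wide <= narrow


def test_required_sample_size_low_proportion_order_of_magnitude():
    n = required_sample_size(0.011, 0.005, 0.026)
    assert 300 <= n <= 1500


def test_required_sample_size_invalid():
    with pytest.raises(ValueError):
        required_sample_size(0.5, 0.6, 0.7)


def _candidate_pool(n=40):
    return [ScoredPair(f"A{i:03d}", f"B{i:03d}", 0.95) for i in range(n)]


def test_sample_candidates_determinism_and_full_pool():
    pool = _candidate_pool()
    r = ScoreRange(0.9, 1.0)
    s1 = sample_candidates(pool, r, 10, seed=7)
    s2 = sample_candidates(pool, r, 10, seed=7)
    assert [(p.id_a, p.id_b) for p in s1.pairs] == \
           [(p.id_a, p.id_b) for p in s2.pairs]
    full = sample_candidates(pool, r, len(pool), seed=1)
    assert {p.id_a for p in full.pairs} == {p.id_a for p in pool}
    with pytest.raises(ValueError):
        sample_candidates(pool, r, len(pool) + 1, seed=1)


def test_sample_candidates_uniformity():
    """Inclusion frequency of any pair is ~ n/pool over repeated draws."""
    pool = _candidate_pool(20)
    r = ScoreRange(0.9, 1.0)
    n, reps = 5, 4000
    counts = {p.id_a: 0 for p in pool}
    for seed in range(reps):
        for p in sample_candidates(pool, r, n, seed=seed).pairs:
            counts[p.id_a] += 1
    expect = reps * n / len(pool)
    se = math.sqrt(reps * (n / len(pool)) * (1 - n / len(pool)))
    for c in counts.values():
        assert abs(c - expect) <= 3.5 * se


def test_model_fit_and_summary():
    data = pd.DataFrame({
        "lo": [0.7, 0.8, 0.9], "hi": [0.8, 0.9, 1.0],
        "x": [7, 13, 89], "n": [125, 100, 209],
        "n_candidates": [34_946, 17_423, 12_664],
        "k_known": [2_194, 3_489, 5_805],
    })
    model = HiddenDuplicateModel(data, total_known_pairs=15_805,
                                 n_unique_trials=271_280, coverage=0.76)
    res = model.fit()
    assert len(res.range_estimates) == 3
    assert isinstance(res.overall, OverallEstimate)
    text = res.summary()
    assert "% hidden" in text and "Coverage" in text
    frame = res.to_frame()
    assert list(frame["x"]) == [7, 13, 89]
    # coverage derived from k_known when not supplied
    auto = HiddenDuplicateModel(data, total_known_pairs=15_805)
    assert auto.coverage == pytest.approx((2_194 + 3_489 + 5_805) / 15_805)


def test_round_half_away():
    assert round_half_away(0.5) == 1
    assert round_half_away(1.5) == 2
    assert round_half_away(-0.5) == -1
    assert round_half_away(2.4) == 2
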