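"""Ratios against complete counts and the two Wilcoxon tests."""

import datetime as dt
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from hauloutsurvey import (
    AbundanceEstimate,
    ComparisonRecord,
    compare_to_complete,
    count_reduction_percent,
    counting_time_hours,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from hauloutsurvey.synthetic import simulate_land_count

D = dt.date(2019, 9, 1)


def _est(point, site="s", method="direct_extrapolation"):
    return AbundanceEstimate(method=method, site_id=site, survey_date=D,
                             point=point, ci_lower=point, ci_upper=point)


class TestCompareToComplete:
    def test_identity_and_arithmetic(self):
        recs, summary, _ = compare_to_complete(
            [_est(100.0), _est(110.0, site="t")],
            {("s", D): 100.0, ("t", D): 100.0})
        assert recs[0].ratio == 1.0 and recs[0].percent_deviation == 0.0
        assert recs[1].ratio == pytest.approx(1.10)
        assert recs[1].percent_deviation == pytest.approx(10.0)
        assert summary["n_compared"] == 2

    def test_unmatched_estimates_reported(self):
        recs, _, uncompared = compare_to_complete([_est(50.0)], {})
        assert recs == [] and len(uncompared) == 1

    def test_zero_complete_count_rejected(self):
        with pytest.raises(ValueError, match="complete count"):
            compare_to_complete([_est(50.0)], {("s", D): 0.0})

    @given(st.floats(1, 1e6), st.floats(1, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_deviation_ratio_identity(self, pred, comp):
        r = ComparisonRecord(site_id="s", survey_date=D, method="m",
                             predicted=pred, complete=comp)
        assert r.percent_deviation == pytest.approx(100 * (r.ratio - 1), rel=1e-9)

    def test_land_bias_recovered_in_ratios(self, rng):
        # engineered 0.6 undercount shows up as a ~0.6 median ratio
        completes = rng.integers(2000, 30_000, size=60)
        recs = []
        for i, c in enumerate(completes):
            land = simulate_land_count(int(c), 0.6, noise_cv=0.1, rng=rng)
            recs.append(ComparisonRecord(site_id=f"s{i}", survey_date=D,
                                         method="land_visual",
                                         predicted=land, complete=int(c)))
        assert np.median([r.ratio for r in recs]) == pytest.approx(0.6, abs=0.05)


def _signed_rank_enumeration(d):
    """Brute-force null distribution of V over all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    v_obs = ranks[d > 0].sum()
    vs = [np.sum([r for r, s in zip(ranks, signs) if s])
          for signs in itertools.product([False, True], repeat=len(d))]
    vs = np.array(vs)
    p = min(1.0, 2 * min((vs <= v_obs + 1e-9).mean(), (vs >= v_obs - 1e-9).mean()))
    return v_obs, p


class TestSignedRank:
    def test_all_positive_shift_n5(self):
        x = np.arange(5) + 10.0
        r = wilcoxon_signed_rank(x, x - 1.0)
        assert r.statistic == 15.0
        assert r.p_value == pytest.approx(2 / 32)
        assert r.method == "exact"

    def test_single_nonzero_pair(self):
        r = wilcoxon_signed_rank([1, 1, 5.0], [1, 1, 4.0])
        assert r.n == 1 and r.n_zero_dropped == 2
        assert r.statistic in (0.0, 1.0)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, 8)
        v_o, p_o = _signed_rank_enumeration(d)
        r = wilcoxon_signed_rank(d)
        assert r.statistic == pytest.approx(v_o)
        assert r.p_value == pytest.approx(p_o, abs=1e-12)

    def test_enumeration_with_tied_magnitudes(self):
        d = np.array([1.0, -1.0, 2.0, 2.0, -3.0, 4.0, 4.0])
        v_o, p_o = _signed_rank_enumeration(d)
        r = wilcoxon_signed_rank(d)
        assert r.statistic == pytest.approx(v_o)
        assert r.p_value == pytest.approx(p_o, abs=1e-12)

    @given(st.lists(st.integers(-50, 50), min_size=4, max_size=12).filter(
        lambda d: any(v != 0 for v in d)),
        st.integers(-1000, 1000))
    @settings(max_examples=60, deadline=None)
    def test_invariant_to_common_pair_shift(self, diffs, shift):
        x = np.array(diffs, dtype=float)
        y = np.zeros_like(x)
        r1 = wilcoxon_signed_rank(x, y)
        r2 = wilcoxon_signed_rank(x + shift, y + shift)
        assert r1.statistic == r2.statistic
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_large_n_uses_normal_approximation(self, rng):
        d = rng.normal(0.2, 1.0, 60)
        r = wilcoxon_signed_rank(d)
        assert r.method == "normal_approx"
        assert 0 <= r.p_value <= 1


def _rank_sum_enumeration(x, y):
    """Brute-force null distribution of W over all C(n, nx) labelings."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    nx = len(x)
    w_obs = ranks[:nx].sum()
    ws = np.array([sum(c) for c in itertools.combinations(ranks, nx)])
    p = min(1.0, 2 * min((ws <= w_obs + 1e-9).mean(), (ws >= w_obs - 1e-9).mean()))
    return w_obs, p


class TestRankSum:
    def test_complete_separation_3v3(self):
        r = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert r.statistic == 6.0
        assert r.p_value == pytest.approx(0.1)
        assert r.method == "exact"

    @pytest.mark.parametrize("nx, ny, seed", [(4, 4, 0), (3, 7, 1), (6, 5, 2)])
    def test_matches_enumeration_oracle(self, nx, ny, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.0, 1.0, nx)
        y = rng.normal(0.5, 1.0, ny)
        w_o, p_o = _rank_sum_enumeration(x, y)
        r = wilcoxon_rank_sum(x, y)
        assert r.statistic == pytest.approx(w_o)
        assert r.p_value == pytest.approx(p_o, abs=1e-12)

    def test_swap_symmetry(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(1, 1, 6)
        r_xy = wilcoxon_rank_sum(x, y)
        r_yx = wilcoxon_rank_sum(y, x)
        assert r_xy.p_value == pytest.approx(r_yx.p_value)
        n = len(x) + len(y)
        assert r_xy.statistic + r_yx.statistic == n * (n + 1) / 2

    def test_type_one_error_rate(self, rng):
        # identical distributions: ~5% rejections at alpha = 0.05
        n_tests, alpha = 1000, 0.05
        rejections = sum(
            wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30)).p_value < alpha
            for _ in range(n_tests)
        )
        se = math.sqrt(alpha * (1 - alpha) / n_tests)
        assert abs(rejections / n_tests - alpha) < 3 * se + 0.005

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestCountingEffort:
    def test_counting_time_worked_example(self):
        # 10,000 animals at one per second is about 2.7-2.8 hours
        assert counting_time_hours(10_000) == pytest.approx(10_000 / 3600)

    def test_reduction_percent(self):
        assert count_reduction_percent(1000, 300) == pytest.approx(70.0)
        with pytest.raises(ValueError):
            count_reduction_percent(0, 0)
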