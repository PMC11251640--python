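"""Comparing abundance estimates against complete counts and each other.

Estimates are compared to complete head counts as a ratio and a percent
deviation (100 x (ratio - 1)).  Distribution-free comparisons of densities
use the Wilcoxon signed-rank test (paired, e.g. two counting methods at the
same surveys) and the Wilcoxon rank-sum test (independent samples, e.g.
densities across sites).  Both use midranks for ties, report R-style
statistics (V = sum of positive-difference ranks; W = rank sum of the first
sample), use the exact null distribution for small samples and a normal
approximation with continuity correction otherwise; p-values are two-sided.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .estimators import AbundanceEstimate


@dataclass
class ComparisonRecord:
    """One estimate set against the complete count of the same survey."""

    site_id: str
    survey_date: "dt.date | None"
    method: str
    predicted: float
    complete: float
    ratio: float = 0.0
    percent_deviation: float = 0.0

    def __post_init__(self) -> None:
        if self.complete <= 0:
            raise ValueError(
                f"{self.site_id} {self.survey_date}: complete count must be positive"
            )
        self.ratio = self.predicted / self.complete
        self.percent_deviation = 100.0 * (self.ratio - 1.0)


def compare_to_complete(
    estimates: "list[AbundanceEstimate]",
    complete_counts: "dict[tuple, float]",
) -> tuple[list[ComparisonRecord], dict, list[AbundanceEstimate]]:
    """Match estimates to complete counts by (site_id, survey_date).

    Returns per-pair records, a summary of percent deviations (mean, median,
    2.5 and 97.5 percentiles), and the estimates that had no complete count.
    """
    records, uncompared = [], []
    for est in estimates:
        key = (est.site_id, est.survey_date)
        if key in complete_counts:
            records.append(ComparisonRecord(
                site_id=est.site_id, survey_date=est.survey_date,
                method=est.method, predicted=est.point,
                complete=float(complete_counts[key]),
            ))
        else:
            uncompared.append(est)
    if records:
        dev = np.array([r.percent_deviation for r in records])
        summary = {
            "n_compared": len(records),
            "mean_percent_deviation": float(dev.mean()),
            "median_percent_deviation": float(np.median(dev)),
            "p2.5_percent_deviation": float(np.percentile(dev, 2.5)),
            "p97.5_percent_deviation": float(np.percentile(dev, 97.5)),
        }
    else:
        summary = {"n_compared": 0}
    return records, summary, uncompared


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    n: int                 # effective sample size(s) used
    method: str            # "exact" or "normal_approx"
    n_zero_dropped: int = 0


def _dist_pvalue_two_sided(pmf: np.ndarray, stat_scaled: int) -> float:
    """Two-sided p from a discrete null pmf over scaled statistic values."""
    cdf_le = pmf[: stat_scaled + 1].sum()
    cdf_ge = pmf[stat_scaled:].sum()
    return float(min(1.0, 2.0 * min(cdf_le, cdf_ge)))


def wilcoxon_signed_rank(
    x,
    y=None,
    continuity_correction: bool = True,
    exact_max_n: int = 25,
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped (their number is reported); tied absolute
    differences get midranks.  V is the sum of ranks of positive
    differences.  For n <= ``exact_max_n`` the exact null distribution is
    computed by dynamic programming over sign assignments; above that a
    normal approximation with tie correction and (optionally) a 0.5
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    nz = d != 0
    dropped = int((~nz).sum())
    d = d[nz]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        scaled = np.rint(2 * ranks).astype(int)   # midranks are half-integers
        total = int(scaled.sum())
        # pmf of the sum of included scaled ranks under random signs
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in scaled:
            counts[r:] += counts[: total + 1 - r].copy()
        pmf = counts / counts.sum()
        p = _dist_pvalue_two_sided(pmf, int(round(2 * v)))
        return WilcoxonResult(v, p, n, "exact", dropped)

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts.astype(float) ** 3 - tie_counts).sum() / 48.0
    z = v - mean
    if continuity_correction:
        z -= 0.5 * np.sign(z)
    z /= np.sqrt(var)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(v, p, n, "normal_approx", dropped)


def wilcoxon_rank_sum(
    x,
    y,
    continuity_correction: bool = True,
    exact_max_n: int = 10,
) -> WilcoxonResult:
    """Two-sample Wilcoxon rank-sum test.

    W is the sum of (mid)ranks of ``x`` in the pooled sample.  The exact
    null distribution (enumeration over rank subsets, by dynamic
    programming) is used when min(n_x, n_y) <= ``exact_max_n`` and there are
    no ties; otherwise a normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:nx].sum())
    nn = nx + ny
    has_ties = np.unique(pooled).size < nn

    if min(nx, ny) <= exact_max_n and not has_ties:
        # number of nx-subsets of {1..nn} with each possible rank sum
        max_sum = nn * (nn + 1) // 2
        table = np.zeros((nx + 1, max_sum + 1))
        table[0, 0] = 1.0
        for r in range(1, nn + 1):
            for k in range(min(r, nx), 0, -1):
                table[k, r:] += table[k - 1, : max_sum + 1 - r]
        pmf = table[nx] / table[nx].sum()
        p = _dist_pvalue_two_sided(pmf, int(round(w)))
        return WilcoxonResult(w, p, min(nx, ny), "exact")

    mean = nx * (nn + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts.astype(float) ** 3 - tie_counts).sum() / (nn * (nn - 1))
    var = nx * ny / 12.0 * ((nn + 1) - tie_term)
    z = w - mean
    if continuity_correction:
        z -= 0.5 * np.sign(z)
    z /= np.sqrt(var)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(w, p, min(nx, ny), "normal_approx")


def counting_time_hours(n_animals: float, rate_per_second: float = 1.0) -> float:
    """Manual counting effort in hours at a constant per-animal rate."""
    if rate_per_second <= 0:
        raise ValueError("rate must be positive")
    return n_animals / rate_per_second / 3600.0


def count_reduction_percent(total_count: float, counted: float) -> float:
    """Percent of animals that never had to be counted individually:
    100 x (1 - counted / total)."""
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    return 100.0 * (1.0 - counted / total_count)
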