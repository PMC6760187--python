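"""Robust summaries, normality screening, and nonparametric comparisons.

Quantitative results are reported as median [Q1-Q3] (linear-interpolation
quantiles); group comparisons use the two-sided Mann-Whitney rank-sum
test (exact for small tie-free samples) and the Wilcoxon signed-rank test
for paired designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GroupSummary:
    median: float
    q1: float
    q3: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles must satisfy q1 <= median <= q3")

    def __str__(self) -> str:
        return f"{self.median:g} [{self.q1:g}-{self.q3:g}] (n={self.n})"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    null_hypothesis: str
    n: tuple[int, ...]
    method: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def summarize(values) -> GroupSummary:
    """Median and quartiles by linear interpolation between order statistics."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError("sample contains non-finite values")
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])
    return GroupSummary(median=float(med), q1=float(q1), q3=float(q3), n=arr.size)


def normality_screen(values) -> TestResult:
    """Jarque-Bera screen: n/6 * (S^2 + (K-3)^2 / 4) against chi-square(2).

    Refuses samples of fewer than 8 observations; the chi-square reference
    is asymptotic, so small-n p-values are recorded as approximate.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 8:
        raise ValueError(f"normality screen needs n >= 8 observations, got {n}")
    centred = arr - arr.mean()
    m2 = np.mean(centred**2)
    if m2 == 0:
        raise ValueError("sample has zero variance")
    skew = np.mean(centred**3) / m2**1.5
    kurt = np.mean(centred**4) / m2**2
    statistic = n / 6.0 * (skew**2 + (kurt - 3.0) ** 2 / 4.0)
    p = float(sps.chi2.sf(statistic, df=2))
    return TestResult(
        statistic=float(statistic),
        p_value=p,
        test_name="jarque_bera",
        null_hypothesis="the sample is drawn from a normal distribution",
        n=(n,),
        method="chi2(2) asymptotic",
        extra={"skewness": float(skew), "kurtosis": float(kurt), "small_n": n < 30},
    )


_EXACT_RANKSUM_MAX_N = 12
_EXACT_SIGNED_RANK_MAX_N = 15


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size


def rank_sum_test(group_a, group_b, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney rank-sum comparison of two independent groups.

    Exact null distribution when both groups have at most 12 observations
    and no ties; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    exact = (
        a.size <= _EXACT_RANKSUM_MAX_N
        and b.size <= _EXACT_RANKSUM_MAX_N
        and not _has_ties(a, b)
    )
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name="mann_whitney_u",
        null_hypothesis="the two groups share the same distribution",
        n=(a.size, b.size),
        method=method,
        extra={"alternative": alternative},
    )


def paired_rank_test(values_a, values_b, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test on per-pair differences.

    Zero differences are dropped (and counted); the exact distribution is
    used for up to 15 non-zero pairs.  A fully degenerate sample (all
    differences zero) returns p = 1 with a ``degenerate`` flag.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError(f"paired samples differ in length ({a.size} vs {b.size})")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = a - b
    n_zero = int(np.sum(diffs == 0))
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return TestResult(
            statistic=0.0,
            p_value=1.0,
            test_name="wilcoxon_signed_rank",
            null_hypothesis="the paired differences are symmetric about zero",
            n=(a.size,),
            method="degenerate",
            extra={"degenerate": True, "n_zero_differences": n_zero},
        )
    method = "exact" if nonzero.size <= _EXACT_SIGNED_RANK_MAX_N else "approx"
    res = sps.wilcoxon(nonzero, alternative=alternative, method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name="wilcoxon_signed_rank",
        null_hypothesis="the paired differences are symmetric about zero",
        n=(a.size,),
        method=method,
        extra={
            "degenerate": False,
            "n_zero_differences": n_zero,
            "alternative": alternative,
        },
    )


def significance_stars(p_value: float) -> str:
    """Star rendering at the 0.05 / 0.01 / 0.001 levels."""
    if not 0.0 <= p_value <= 1.0:
        raise ValueError("p_value must lie in [0, 1]")
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"
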