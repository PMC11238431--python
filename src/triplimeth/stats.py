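"""Self-contained statistical kernel used by every analysis stage.

Implements the tests named in the analyses: Benjamini-Hochberg FDR
adjustment, the Wilcoxon rank-sum (Mann-Whitney U) and signed-rank tests
with *exact* small-sample permutation distributions, one-way ANOVA, and the
pooled-variance two-sample t test.

Exactness policy
----------------
* rank-sum: the exact permutation distribution of the rank sum is computed
  by dynamic programming over subsets of the pooled mid-ranks whenever
  ``min(|x|, |y|) <= 8`` and no tied value spans the two groups; otherwise a
  normal approximation with tie correction and continuity correction is
  used.  The DP is mathematically identical to complete enumeration of the
  C(n+m, n) label assignments.
* signed-rank: zero differences are discarded (Wilcoxon's convention); the
  exact distribution is computed by enumerating all 2**n sign patterns when
  n <= 12, otherwise a tie-corrected normal approximation is used.

Mid-ranks are used for ties everywhere, and the tie correction enters the
approximate variances.  Every result records which method produced its
p-value so downstream tables are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as _spstats

__all__ = [
    "TestResult",
    "benjamini_hochberg",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "one_way_anova",
    "two_sample_t",
    "percent_half_up",
]

# thresholds below which the exact permutation distributions are used;
# chosen so the enumerations run in milliseconds
EXACT_RANK_SUM_MIN_GROUP = 8
EXACT_SIGNED_RANK_N = 12

_ALTERNATIVES = ("two_sided", "less", "greater")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    Attributes
    ----------
    statistic : float
        The test statistic (U for rank-sum, W+ for signed-rank, F for
        ANOVA, t for the t test).
    p_value : float
        In [0, 1].
    method : str
        One of ``exact``, ``normal_approx``, ``f_distribution``,
        ``t_distribution`` - how the p-value was obtained.
    n_effective : int
        Number of observations actually used (after discarding zero
        differences, for the signed-rank test).
    """

    statistic: float
    p_value: float
    method: str
    n_effective: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")
        if self.n_effective < 0:
            raise ValueError("n_effective must be >= 0")


def _check_alternative(alternative: str) -> str:
    alt = alternative.replace("-", "_")
    if alt not in _ALTERNATIVES:
        raise ValueError(
            f"alternative must be one of {_ALTERNATIVES}, got {alternative!r}"
        )
    return alt


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up FDR adjustment; returns q-values in the input order.

    q_(i) = min_{j >= i} (p_(j) * n / j) on the sorted p-values, capped at
    1.  Raises on an empty input or on p-values outside [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("benjamini_hochberg requires a non-empty 1-d list of p-values")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney U)
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    return _spstats.rankdata(values, method="average")

def _rank_sum_exact_pmf(doubled_ranks: np.ndarray, n_x: int):
    """Distribution of the doubled rank sum of a uniformly random size-n_x
    subset of the pooled mid-ranks.

    Returns (probabilities, offset) such that ``probabilities[s]`` is the
    probability that the doubled rank sum equals ``s`` (s from 0).  Doubling
    makes mid-ranks integral.  Equivalent to enumerating all C(N, n_x)
    labelings.
    """
    total = int(doubled_ranks.sum())
    # dp[k, s] = number of size-k subsets with doubled-rank sum s
    dp = np.zeros((n_x + 1, total + 1))
    dp[0, 0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        # iterate k downward so each item is used at most once
        for k in range(n_x, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    counts = dp[n_x]
    return counts / counts.sum()


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided") -> TestResult:
    """Unpaired two-sample Wilcoxon rank-sum test.

    ``alternative='less'`` tests that x is stochastically smaller than y.
    The statistic is the Mann-Whitney U of the first sample.
    """
    alt = _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r_x = float(ranks[:n].sum())
    u = r_x - n * (n + 1) / 2.0

    cross_ties = bool(np.intersect1d(np.unique(x), np.unique(y)).size)
    use_exact = min(n, m) <= EXACT_RANK_SUM_MIN_GROUP and not cross_ties

    if use_exact:
        doubled = np.rint(2.0 * ranks).astype(np.int64)
        nn = min(n, m)
        pmf = _rank_sum_exact_pmf(doubled, nn)
        if nn == n:
            obs = int(round(2.0 * r_x))
        else:  # symmetric: enumerate the smaller group
            obs = int(round(2.0 * float(ranks[n:].sum())))
        cdf = np.cumsum(pmf)
        p_le = float(cdf[obs])
        p_ge = float(pmf[obs:].sum())
        if nn == n:
            p_less, p_greater = p_le, p_ge
        else:  # small-U of y corresponds to large-U of x
            p_less, p_greater = p_ge, p_le
        if alt == "less":
            p = p_less
        elif alt == "greater":
            p = p_greater
        else:
            p = min(1.0, 2.0 * min(p_less, p_greater))
        return TestResult(u, p, "exact", n + m)

    # normal approximation with tie correction and continuity correction
    big_n = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (big_n * (big_n - 1))
    mu = n * m / 2.0
    sigma2 = n * m / 12.0 * ((big_n + 1) - tie_term)
    if sigma2 <= 0:  # all values identical
        return TestResult(u, 1.0, "normal_approx", big_n)
    sigma = np.sqrt(sigma2)
    if alt == "less":
        z = (u - mu + 0.5) / sigma
        p = float(_spstats.norm.cdf(z))
    elif alt == "greater":
        z = (u - mu - 0.5) / sigma
        p = float(_spstats.norm.sf(z))
    else:
        z = (abs(u - mu) - 0.5) / sigma
        p = float(min(1.0, 2.0 * _spstats.norm.sf(max(z, 0.0))))
    return TestResult(u, p, "normal_approx", big_n)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_rank_exact_pmf(doubled_ranks: np.ndarray):
    """Distribution of the doubled W+ over all 2**n equally likely sign
    patterns (each rank independently positive or negative)."""
    total = int(doubled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    return dist


def wilcoxon_signed_rank(x, y, alternative: str = "two_sided") -> TestResult:
    """Paired Wilcoxon signed-rank test on differences x - y.

    Zero differences are discarded before ranking; ``n_effective`` reports
    the remainder.  If every difference is zero the test returns p = 1.0
    with ``n_effective = 0`` and a warning (no evidence either way).
    ``alternative='greater'`` tests that x exceeds y.
    """
    alt = _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("x and y must be paired, equal-length, non-empty samples")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn(
            "all paired differences are zero; signed-rank test carries no evidence",
            stacklevel=2,
        )
        return TestResult(0.0, 1.0, "exact", 0)

    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_SIGNED_RANK_N:
        doubled = np.rint(2.0 * ranks).astype(np.int64)
        pmf = _signed_rank_exact_pmf(doubled)
        obs = int(round(2.0 * w_plus))
        cdf = np.cumsum(pmf)
        p_le = float(cdf[obs])
        p_ge = float(pmf[obs:].sum())
        if alt == "greater":
            p = p_ge
        elif alt == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(w_plus, p, "exact", n)

    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    mu = n * (n + 1) / 4.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        (tie_counts**3 - tie_counts).sum()
    ) / 48.0
    if sigma2 <= 0:
        return TestResult(w_plus, 1.0, "normal_approx", n)
    sigma = np.sqrt(sigma2)
    if alt == "greater":
        z = (w_plus - mu - 0.5) / sigma
        p = float(_spstats.norm.sf(z))
    elif alt == "less":
        z = (w_plus - mu + 0.5) / sigma
        p = float(_spstats.norm.cdf(z))
    else:
        z = (abs(w_plus - mu) - 0.5) / sigma
        p = float(min(1.0, 2.0 * _spstats.norm.sf(max(z, 0.0))))
    return TestResult(w_plus, p, "normal_approx", n)


# ---------------------------------------------------------------------------
# One-way ANOVA and the pooled t test
# ---------------------------------------------------------------------------

def one_way_anova(groups) -> TestResult:
    """One-way fixed-effects ANOVA across two or more groups.

    F = MS_between / MS_within with (k-1, N-k) degrees of freedom.  A fully
    degenerate input (zero between- and within-group variance) yields F = 0,
    p = 1.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g in gs:
        if g.size < 2:
            raise ValueError("every group must have at least two observations")
    k = len(gs)
    big_n = sum(g.size for g in gs)
    grand = sum(float(g.sum()) for g in gs) / big_n
    ssb = sum(g.size * (float(g.mean()) - grand) ** 2 for g in gs)
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in gs)
    df_b, df_w = k - 1, big_n - k
    msb = ssb / df_b
    msw = ssw / df_w
    if msw == 0.0:
        if msb == 0.0:
            return TestResult(0.0, 1.0, "f_distribution", big_n)
        return TestResult(float("inf"), 0.0, "f_distribution", big_n)
    f = msb / msw
    p = float(_spstats.f.sf(f, df_b, df_w))
    return TestResult(f, p, "f_distribution", big_n)


def two_sample_t(x, y) -> TestResult:
    """Pooled-variance two-sample Student t test (two-sided).

    For any two groups t**2 equals the one-way ANOVA F (checked in the
    test suite).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least two observations")
    n, m = x.size, y.size
    df = n + m - 2
    sp2 = (float(((x - x.mean()) ** 2).sum()) + float(((y - y.mean()) ** 2).sum())) / df
    diff = float(x.mean() - y.mean())
    if sp2 == 0.0:
        if diff == 0.0:
            return TestResult(0.0, 1.0, "t_distribution", n + m)
        return TestResult(float("inf") if diff > 0 else float("-inf"), 0.0,
                          "t_distribution", n + m)
    t = diff / np.sqrt(sp2 * (1.0 / n + 1.0 / m))
    p = float(2.0 * _spstats.t.sf(abs(t), df))
    return TestResult(t, min(p, 1.0), "t_distribution", n + m)


# ---------------------------------------------------------------------------
# Shared numeric helper
# ---------------------------------------------------------------------------

def percent_half_up(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """100 * numerator / denominator rounded half-up to ``ndigits`` places.

    Uses exact decimal arithmetic so printed percentages match hand
    calculation (e.g. 116888/127681 -> 91.55).
    """
    if denominator == 0:
        raise ZeroDivisionError("denominator must be non-zero")
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-ndigits)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))
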