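"""Self-contained implementations of the statistical tests used downstream.

Four tests cover everything the analysis reports:

* two-proportion Z-test (pooled variance) for percent-active and
  percent-activity-inducing comparisons;
* Mann-Whitney U for firing-rate and induced-spike comparisons, with an
  exact permutation distribution (tie-aware) on small samples;
* Mann-Kendall trend test applied to short sequences of group means
  (development over weeks, dose-response over concentrations), with the
  exact small-sample tail;
* Fisher's method for combining independent p-values.

The statistics themselves are computed here so every number is auditable;
scipy supplies only the normal and chi-square distribution functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm

__all__ = [
    "TestResult",
    "two_proportion_z",
    "mann_whitney_u",
    "mann_kendall",
    "fishers_method",
]

_SIDES = ("two-sided", "greater", "less")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    sided: str
    method: str
    n: int
    m: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _check_sided(sided: str) -> None:
    if sided not in _SIDES:
        raise ValueError(f"sided must be one of {_SIDES}, got {sided!r}")


# ---------------------------------------------------------------------------
# two-proportion Z

def two_proportion_z(successes1: int, n1: int, successes2: int, n2: int,
                     sided: str = "two-sided") -> TestResult:
    """Pooled two-proportion Z-test.

    ``greater`` tests whether proportion 1 exceeds proportion 2.  A pooled
    proportion of exactly 0 or 1 makes the variance degenerate; p = 1 is
    returned with a warning in that case.
    """
    _check_sided(sided)
    if not (0 <= successes1 <= n1 and 0 <= successes2 <= n2):
        raise ValueError("successes must lie in [0, n]")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    pooled = (successes1 + successes2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("degenerate pooled proportion; p-value set to 1", stacklevel=2)
        return TestResult(0.0, 1.0, sided, "two-proportion Z (pooled)", n1, n2)
    p1, p2 = successes1 / n1, successes2 / n2
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    if sided == "two-sided":
        p = 2 * _norm.sf(abs(z))
    elif sided == "greater":
        p = _norm.sf(z)
    else:
        p = _norm.cdf(z)
    return TestResult(float(z), float(min(p, 1.0)), sided, "two-proportion Z (pooled)", n1, n2)


# ---------------------------------------------------------------------------
# Mann-Whitney U

def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size, dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


@lru_cache(maxsize=64)
def _ranksum_distribution(doubled_ranks: tuple[int, ...], n: int) -> np.ndarray:
    """Exact permutation counts of the sample-1 rank sum (in doubled units).

    ``counts[s]`` is the number of n-subsets of the pooled ranks whose
    doubled-rank sum equals s.  Tie structure is handled exactly because
    the DP runs over the observed (mid)ranks.
    """
    total = sum(doubled_ranks)
    counts = np.zeros((n + 1, total + 1))
    counts[0, 0] = 1.0
    for r in doubled_ranks:
        for k in range(min(n, 1_000_000), 0, -1):
            counts[k, r:] += counts[k - 1, : total + 1 - r]
    return counts[n]


def mann_whitney_u(sample_a, sample_b, sided: str = "two-sided",
                   method: str = "auto") -> TestResult:
    """Mann-Whitney U with midrank tie handling.

    U counts pairs where an ``a`` observation exceeds a ``b`` observation
    (ties count 1/2).  The p-value is exact (full permutation distribution,
    conditional on observed ranks) when n*m <= 400, otherwise a
    tie-corrected normal approximation with continuity correction.
    ``greater`` tests whether ``a`` tends to exceed ``b``.
    """
    _check_sided(sided)
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    r_a = ranks[:n].sum()
    u = r_a - n * (n + 1) / 2.0

    if method == "auto":
        method = "exact" if n * m <= 400 else "normal"

    if method == "exact":
        doubled = tuple(int(round(2 * r)) for r in ranks)
        dist = _ranksum_distribution(tuple(sorted(doubled)), n)
        total = dist.sum()
        s_obs = int(round(2 * r_a))
        p_le = dist[: s_obs + 1].sum() / total
        p_ge = dist[s_obs:].sum() / total
        if sided == "greater":
            p = p_ge
        elif sided == "less":
            p = p_le
        else:
            p = min(1.0, 2 * min(p_le, p_ge))
        label = "Mann-Whitney U (exact)"
    else:
        mu = n * m / 2.0
        total_n = n + m
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / (total_n * (total_n - 1))
        var = n * m / 12.0 * (total_n + 1 - tie_term)
        if var <= 0:
            warnings.warn("all observations tied; p-value set to 1", stacklevel=2)
            return TestResult(float(u), 1.0, sided, "Mann-Whitney U (normal)", n, m)
        sd = np.sqrt(var)
        if sided == "greater":
            p = _norm.sf((u - 0.5 - mu) / sd)
        elif sided == "less":
            p = _norm.cdf((u + 0.5 - mu) / sd)
        else:
            z = (abs(u - mu) - 0.5) / sd
            p = 2 * _norm.sf(max(z, 0.0))
        label = "Mann-Whitney U (normal)"
    return TestResult(float(u), float(min(p, 1.0)), sided, label, n, m)


# ---------------------------------------------------------------------------
# Mann-Kendall

@lru_cache(maxsize=32)
def _inversion_counts(n: int) -> np.ndarray:
    """Number of permutations of n items with k inversions, k = 0..n(n-1)/2.

    Classic polynomial product prod_{j=1}^{n-1} (1 + q + ... + q^j);
    the null distribution of Kendall's S follows via S = n(n-1)/2 - 2k.
    """
    counts = np.ones(1)
    for j in range(1, n):
        kernel = np.ones(j + 1)
        counts = np.convolve(counts, kernel)
    return counts


def mann_kendall(sequence, sided: str = "two-sided") -> TestResult:
    """Mann-Kendall trend test on an ordered sequence (e.g. of group means).

    S = sum_{i<j} sign(x_j - x_i).  For n <= 10 without ties the exact
    permutation tail is used; otherwise the tie-corrected normal
    approximation with continuity correction.  ``greater`` tests for an
    increasing trend, ``less`` for a decreasing one.
    """
    _check_sided(sided)
    x = np.asarray(sequence, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points for a trend test")
    diffs = np.sign(x[None, :] - x[:, None])
    s = float(np.triu(diffs, k=1).sum())

    has_ties = np.unique(x).size < n
    if n <= 10 and not has_ties:
        counts = _inversion_counts(n)
        total = counts.sum()
        max_s = n * (n - 1) // 2
        s_values = max_s - 2 * np.arange(counts.size)  # S for each inversion count
        p_ge = counts[s_values >= s].sum() / total
        p_le = counts[s_values <= s].sum() / total
        if sided == "greater":
            p = p_ge
        elif sided == "less":
            p = p_le
        else:
            p = min(1.0, 2 * min(p_ge, p_le))
        label = "Mann-Kendall (exact)"
    else:
        _, tie_counts = np.unique(x, return_counts=True)
        var = (n * (n - 1) * (2 * n + 5)
               - np.sum(tie_counts * (tie_counts - 1) * (2 * tie_counts + 5))) / 18.0
        if var <= 0:
            return TestResult(s, 1.0, sided, "Mann-Kendall (normal)", n)
        sd = np.sqrt(var)
        if s > 0:
            z = (s - 1) / sd
        elif s < 0:
            z = (s + 1) / sd
        else:
            z = 0.0
        if sided == "greater":
            p = _norm.sf(z)
        elif sided == "less":
            p = _norm.cdf(z)
        else:
            p = 2 * _norm.sf(abs(z))
        label = "Mann-Kendall (normal)"
    return TestResult(s, float(min(p, 1.0)), sided, label, n)


# ---------------------------------------------------------------------------
# Fisher's method

def fishers_method(p_values) -> TestResult:
    """Fisher's combined probability: chi2 = -2 sum ln p on 2k df."""
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(ps > 1) or np.any(ps < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(ps == 0):
        warnings.warn("p-value of 0 supplied; combined p is 0", stacklevel=2)
        return TestResult(np.inf, 0.0, "two-sided", "Fisher's method", int(ps.size))
    stat = -2.0 * np.log(ps).sum()
    p = _chi2.sf(stat, df=2 * ps.size)
    return TestResult(float(stat), float(p), "two-sided", "Fisher's method", int(ps.size))
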