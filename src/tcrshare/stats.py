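"""Rank statistics used throughout: Spearman correlation and Mann-Whitney U.

Thin, explicit wrappers over scipy.stats that pin down the conventions the
analyses rely on (tie handling, exact small-sample p-values, degenerate-input
flags) so every module reports comparable numbers.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ValidationError


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    flag: str | None = None  # e.g. "CONSTANT", "ALL_TIED"


def spearman_correlation(x, y, method: str = "auto") -> TestResult:
    """Spearman rank correlation with average ranks for ties.

    ``method``: "t" (t-distribution approximation), "exact" (full permutation
    null, only for n ≤ 8), or "auto" (t approximation, the convention used for
    reported correlations). The exact permutation p uses the mid-p convention
    (half weight on permutations exactly as extreme as observed): the null is
    very discrete at these n and mid-p is the comparable quantity for a
    continuous approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValidationError("Spearman correlation needs n ≥ 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(float("nan"), float("nan"), (n,), "spearman", flag="CONSTANT")
    rho, p_t = sps.spearmanr(x, y)
    if method in ("auto", "t"):
        return TestResult(float(rho), float(p_t), (n,), "spearman-t")
    if method == "exact":
        if n > 8:
            raise ValidationError("exact permutation Spearman only for n ≤ 8")
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        observed = abs(rho)
        more = ties = total = 0
        for perm in itertools.permutations(range(n)):
            r, _ = sps.spearmanr(rx, ry[list(perm)])
            total += 1
            if abs(r) > observed + 1e-9:
                more += 1
            elif abs(r) >= observed - 1e-9:
                ties += 1
        return TestResult(float(rho), (more + 0.5 * ties) / total, (n,), "spearman-exact")
    raise ValidationError(f"unknown method {method!r}")


def spearman_ci(rho: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Spearman correlation (n > 3)."""
    if n <= 3 or not np.isfinite(rho):
        return (float("nan"), float("nan"))
    z = math.atanh(max(min(rho, 1 - 1e-15), -1 + 1e-15))
    # Fieller-style standard error for Spearman's rho
    se = math.sqrt(1.06 / (n - 3))
    zcrit = sps.norm.ppf(0.5 + level / 2)
    return (math.tanh(z - zcrit * se), math.tanh(z + zcrit * se))


def mann_whitney_u(group_a, group_b, method: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when min(n) ≤ 8 and there are no ties across the
    pooled sample; tie-corrected normal approximation otherwise. All values
    tied across both groups yields p = 1 with an ALL_TIED flag.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        u = a.size * b.size / 2
        return TestResult(float(u), 1.0, (a.size, b.size), "mann-whitney", flag="ALL_TIED")
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        use_exact = min(a.size, b.size) <= 8 and not has_ties
    elif method == "exact":
        if has_ties:
            raise ValidationError("exact Mann-Whitney p undefined with ties")
        use_exact = True
    elif method == "asymptotic":
        use_exact = False
    else:
        raise ValidationError(f"unknown method {method!r}")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact" if use_exact else "asymptotic")
    return TestResult(
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        (a.size, b.size),
        "mann-whitney-exact" if use_exact else "mann-whitney-normal",
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-tolerant, monotone)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv)
    adj = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out
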