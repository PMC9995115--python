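"""Sample-size-based rarefaction and extrapolation of Hill numbers q=0, q=1.

Richness interpolation uses the exact hypergeometric expectation
``Ŝ(m) = S_obs − Σ_i C(n−n_i, m)/C(n, m)`` (computed with log-binomials);
richness extrapolation uses the Chao1 estimate of undetected richness.
Shannon (Hill q=1) interpolation is a seeded Monte-Carlo average of the
entropy of hypergeometric subsamples — chosen over the closed-form estimator
because it can be validated against exhaustive subset enumeration on toy
communities — and extrapolation returns a coverage-adjusted asymptotic
entropy plateau.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .errors import ValidationError
from .io import Repertoire
from .stats import TestResult, mann_whitney_u


@dataclass(frozen=True)
class AbundanceVector:
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.counts or any(c < 1 for c in self.counts):
            raise ValidationError("abundance vector needs ≥1 species, all counts ≥ 1")

    @classmethod
    def from_repertoire(cls, rep: Repertoire) -> "AbundanceVector":
        return cls(tuple(sorted(rep.junction_counts().values(), reverse=True)))

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def s_obs(self) -> int:
        return len(self.counts)

    @property
    def f1(self) -> int:
        return sum(1 for c in self.counts if c == 1)

    @property
    def f2(self) -> int:
        return sum(1 for c in self.counts if c == 2)


@dataclass(frozen=True)
class DiversityCurve:
    q: int
    m_grid: tuple[int, ...]
    estimates: tuple[float, ...]
    regimes: tuple[str, ...]  # INT, OBS, EXT per grid point
    ci_low: tuple[float, ...] | None = None
    ci_high: tuple[float, ...] | None = None

    def at(self, m: int) -> float:
        return self.estimates[self.m_grid.index(m)]


def _log_choose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _chao1_f0(av: AbundanceVector) -> float:
    n, f1, f2 = av.n, av.f1, av.f2
    if f2 > 0:
        return (n - 1) / n * f1 * f1 / (2 * f2)
    return (n - 1) / n * f1 * (f1 - 1) / 2


def rarefied_richness(av: AbundanceVector, m: int) -> float:
    """Expected number of distinct clonotypes in a size-m subsample (m ≤ n)."""
    if m < 1:
        raise ValidationError("m must be ≥ 1")
    n = av.n
    if m > n:
        raise ValidationError("interpolation requires m ≤ n")
    counts = np.asarray(av.counts, dtype=float)
    keep = (n - counts) >= m
    absent = np.zeros(len(counts))
    if keep.any():
        absent[keep] = np.exp(_log_choose(n - counts[keep], m) - _log_choose(n, m))
    return float(av.s_obs - absent.sum())


def extrapolated_richness(av: AbundanceVector, m_extra: int) -> float:
    """Chao1-based expected richness at sample size n + m_extra."""
    f0 = _chao1_f0(av)
    f1, n = av.f1, av.n
    if f0 <= 0 or f1 == 0:
        return float(av.s_obs)
    return float(av.s_obs + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** m_extra))


def _richness_point(av: AbundanceVector, m: int) -> tuple[float, str]:
    if m < 1:
        raise ValidationError("m must be ≥ 1")
    if m < av.n:
        return rarefied_richness(av, m), "INT"
    if m == av.n:
        return float(av.s_obs), "OBS"
    return extrapolated_richness(av, m - av.n), "EXT"


def _bootstrap_ci(
    av: AbundanceVector,
    m_grid: Sequence[int],
    point_fn,
    reps: int,
    rng: np.random.Generator,
    level: float = 0.95,
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Percentile CI from multinomial resamples of the abundance vector."""
    counts = np.asarray(av.counts, dtype=float)
    p = counts / counts.sum()
    samples = np.empty((reps, len(m_grid)))
    for b in range(reps):
        resampled = rng.multinomial(av.n, p)
        boot = AbundanceVector(tuple(int(c) for c in resampled[resampled > 0]))
        samples[b] = [point_fn(boot, min(int(m), boot.n) if int(m) <= av.n else int(m))[0] for m in m_grid]
    alpha = (1 - level) / 2
    lo = np.quantile(samples, alpha, axis=0)
    hi = np.quantile(samples, 1 - alpha, axis=0)
    return tuple(float(x) for x in lo), tuple(float(x) for x in hi)


def rarefy_richness(
    av: AbundanceVector,
    m_grid: Sequence[int],
    bootstrap_reps: int = 0,
    seed: int | np.random.Generator = 0,
) -> DiversityCurve:
    """Hill q=0 rarefaction/extrapolation curve over ``m_grid``.

    ``bootstrap_reps`` > 0 adds seeded percentile confidence bands from
    multinomial resamples of the observed abundances (default off).
    """
    est, reg = zip(*(_richness_point(av, int(m)) for m in m_grid))
    lo = hi = None
    if bootstrap_reps > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        lo, hi = _bootstrap_ci(av, m_grid, _richness_point, bootstrap_reps, rng)
    return DiversityCurve(0, tuple(int(m) for m in m_grid), tuple(est), tuple(reg), lo, hi)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _asymptotic_hill1(av: AbundanceVector) -> float:
    """Coverage-adjusted (Chao-Shen) asymptotic exp(entropy) plateau."""
    n = av.n
    counts = np.asarray(av.counts, dtype=float)
    coverage = 1.0 - av.f1 / n
    if coverage <= 0:
        return float(av.s_obs)
    p_adj = coverage * counts / n
    weights = 1.0 - (1.0 - p_adj) ** n
    h = -(p_adj * np.log(p_adj) / weights).sum()
    return float(np.exp(h))


def rarefy_shannon(
    av: AbundanceVector,
    m_grid: Sequence[int],
    b_reps: int = 200,
    seed: int | np.random.Generator = 0,
) -> DiversityCurve:
    """Hill q=1 curve: exp(expected subsample entropy), Monte-Carlo estimated.

    At m = n the estimate is the (exact) plug-in exp(entropy). Beyond n the
    asymptotic plateau is reported with regime EXT.
    """
    if b_reps < 1:
        raise ValidationError("b_reps must be ≥ 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.asarray(av.counts, dtype=np.int64)
    est, reg = [], []
    for m in m_grid:
        if m < 1:
            raise ValidationError("m must be ≥ 1")
        if m < av.n:
            hs = np.empty(b_reps)
            for b in range(b_reps):
                sub = rng.multivariate_hypergeometric(counts, int(m))
                hs[b] = _entropy(sub.astype(float))
            est.append(float(np.exp(hs.mean())))
            reg.append("INT")
        elif m == av.n:
            est.append(float(np.exp(_entropy(counts.astype(float)))))
            reg.append("OBS")
        else:
            est.append(_asymptotic_hill1(av))
            reg.append("EXT")
    return DiversityCurve(1, tuple(int(m) for m in m_grid), tuple(est), tuple(reg))


@dataclass(frozen=True)
class GroupComparison:
    test: TestResult
    median_a: float
    median_b: float
    at_m: int
    flag: str | None = None


def compare_group_diversity(
    group_a: Sequence[DiversityCurve],
    group_b: Sequence[DiversityCurve],
    at_m: int,
) -> GroupComparison:
    """Two-sided Mann-Whitney on per-sample diversity estimates at a common size."""
    try:
        a = [c.at(at_m) for c in group_a]
        b = [c.at(at_m) for c in group_b]
    except ValueError:
        raise ValidationError(f"every curve must be evaluated at m={at_m}") from None
    flag = None
    if min(len(a), len(b)) < 2:
        flag = "GROUP_TOO_SMALL"
    test = mann_whitney_u(a, b)
    return GroupComparison(test, float(np.median(a)), float(np.median(b)), int(at_m), flag)


def default_m_grid(n: int, points: int = 12, extend: float = 2.0) -> list[int]:
    """Log-ish grid from 1 to extend·n including n itself."""
    grid = np.unique(np.round(np.geomspace(1, max(2, int(extend * n)), points)).astype(int))
    return sorted(set(grid.tolist()) | {n})
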