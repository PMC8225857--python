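"""Coverage-based rarefaction and extrapolation of clonotype richness.

Implements the individual-based (clone-based) richness estimators for Hill
order q = 0: interpolated richness by exact hypergeometric expectation,
sample-coverage estimation, extrapolation through the bias-corrected unseen
clonotype count, bootstrap confidence intervals, and relative diversity of
two communities at a fixed coverage level.

All binomial coefficients are evaluated in log space, so abundance vectors
with totals up to ~1e6 clones are handled without overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import CoverageUnreachableError, InputError

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class AbundanceVector:
    """Positive integer clonotype abundances with frequency-of-frequencies.

    Parameters
    ----------
    abundances:
        Iterable of per-clonotype abundances (all >= 1), or a mapping from
        clonotype key to abundance (keys are discarded).
    """

    def __init__(self, abundances: Iterable[int] | Mapping[object, int]):
        if isinstance(abundances, Mapping):
            abundances = list(abundances.values())
        X = np.asarray(sorted(abundances, reverse=True), dtype=np.int64)
        if X.size == 0:
            raise InputError("abundance vector is empty")
        if np.any(X < 1):
            raise InputError("all abundances must be >= 1")
        self.X = X
        self.n = int(X.sum())
        self.S_obs = int(X.size)
        counts = np.bincount(X)
        self.f = {int(k): int(c) for k, c in enumerate(counts) if k >= 1 and c > 0}

    def f_k(self, k: int) -> int:
        """Number of clonotypes observed exactly k times."""
        return self.f.get(k, 0)

    @property
    def f1(self) -> int:
        return self.f_k(1)

    @property
    def f2(self) -> int:
        return self.f_k(2)

    def __repr__(self) -> str:  # pragma: no cover
        return f"AbundanceVector(n={self.n}, S_obs={self.S_obs}, f1={self.f1}, f2={self.f2})"


def _lchoose(n: np.ndarray | float, k: float) -> np.ndarray:
    """log C(n, k); -inf where the coefficient is zero (k > n or k < 0)."""
    n = np.asarray(n, dtype=float)
    out = np.full(n.shape, -np.inf)
    ok = (n >= k) & (k >= 0)
    nn = n[ok]
    out[ok] = gammaln(nn + 1.0) - gammaln(k + 1.0) - gammaln(nn - k + 1.0)
    return out


def f0_hat(X: AbundanceVector) -> float:
    """Bias-corrected estimate of the number of unseen clonotypes (Chao1 form)."""
    n, f1, f2 = X.n, X.f1, X.f2
    if f1 == 0:
        return 0.0
    if f2 > 0:
        return (n - 1) / n * f1 * f1 / (2.0 * f2)
    return (n - 1) / n * f1 * (f1 - 1) / 2.0


def coverage_hat(X: AbundanceVector, m: int) -> float:
    """Estimated sample coverage of a hypothetical sample of ``m`` clones."""
    if m < 1:
        raise InputError(f"m must be >= 1, got {m}")
    n, f1, f2 = X.n, X.f1, X.f2
    if m < n:
        # 1 - sum_i (X_i/n) C(n-X_i, m)/C(n-1, m)
        log_denom = _lchoose(np.array([n - 1.0]), m)[0]
        log_num = _lchoose(n - X.X.astype(float), m)
        terms = (X.X / n) * np.exp(log_num - log_denom)
        return float(1.0 - terms.sum())
    # reference-sample coverage term
    if f1 == 0:
        return 1.0
    denom = (n - 1) * f1 + 2.0 * f2
    A = (n - 1) * f1 / denom if denom > 0 else 1.0  # n = 1 degenerate case
    m_star = m - n
    return float(1.0 - (f1 / n) * A ** (m_star + 1))


def richness_hat(X: AbundanceVector, m: int | float) -> float:
    """Estimated clonotype richness at sample size ``m`` (Hill order 0).

    Interpolation (m <= n) is the exact expectation of the number of distinct
    clonotypes in a without-replacement subsample of size m.  Extrapolation
    uses the bias-corrected unseen-clonotype estimate.  Non-integer ``m``
    within the range is linearly interpolated between adjacent integers.
    """
    if m < 1:
        raise InputError(f"m must be >= 1, got {m}")
    if isinstance(m, float) and not m.is_integer():
        lo = int(math.floor(m))
        hi = lo + 1
        w = m - lo
        return (1 - w) * richness_hat(X, lo) + w * richness_hat(X, hi)
    m = int(m)
    n = X.n
    if m <= n:
        log_denom = _lchoose(np.array([float(n)]), m)[0]
        log_num = _lchoose(n - X.X.astype(float), m)
        return float(X.S_obs - np.exp(log_num - log_denom).sum())
    f0 = f0_hat(X)
    if f0 == 0.0:
        return float(X.S_obs)
    m_star = m - n
    x = X.f1 / (n * f0 + X.f1)
    # (1-x)^{m*} via exp/log1p: stable for m* up to 1e6 * n
    decay = math.exp(m_star * math.log1p(-x))
    return float(X.S_obs + f0 * (1.0 - decay))


@dataclass(frozen=True)
class CurvePoint:
    m: int
    coverage: float
    richness: float
    ci_lo: float
    ci_hi: float
    regime: str  # interpolated | observed | extrapolated


@dataclass(frozen=True)
class DiversityCurve:
    points: tuple[CurvePoint, ...]
    q: int
    B: int
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "m": p.m,
                    "coverage": p.coverage,
                    "richness": p.richness,
                    "ci_lo": p.ci_lo,
                    "ci_hi": p.ci_hi,
                    "regime": p.regime,
                }
                for p in self.points
            ]
        )


@dataclass(frozen=True)
class RelativeDiversity:
    ratio: float
    ci_lo: float
    ci_hi: float
    coverage_level: float
    m_a: float
    m_b: float
    richness_a: float
    richness_b: float
    B: int


def bootstrap_community(X: AbundanceVector) -> np.ndarray:
    """Probability vector of the coverage-adjusted bootstrap community.

    Observed clonotype probabilities are shrunk so their total equals the
    estimated reference-sample coverage; the estimated coverage deficit is
    spread equally over ceil(f0_hat) unseen clonotypes.
    """
    n = X.n
    p_obs = X.X / n
    C_n = coverage_hat(X, n)
    deficit = 1.0 - C_n
    w = p_obs * (1.0 - p_obs) ** n
    lam = deficit / w.sum() if w.sum() > 0 else 0.0
    p_seen = p_obs * (1.0 - lam * (1.0 - p_obs) ** n)
    f0c = int(math.ceil(f0_hat(X)))
    if f0c > 0 and deficit > 0:
        p = np.concatenate([p_seen, np.full(f0c, deficit / f0c)])
    else:
        p = p_seen
    return p / p.sum()


def _bootstrap_replicates(
    X: AbundanceVector, B: int, rng: np.random.Generator
) -> list[AbundanceVector]:
    p = bootstrap_community(X)
    reps = []
    for _ in range(B):
        counts = rng.multinomial(X.n, p)
        reps.append(AbundanceVector(counts[counts > 0]))
    return reps


def re_curve_with_bootstrap(
    X: AbundanceVector,
    m_grid: Sequence[int],
    B: int = 10,
    seed: int | None = None,
    q: int = 0,
) -> DiversityCurve:
    """Rarefaction/extrapolation curve with normal-approximation bootstrap CIs.

    For each m the CI is richness ± 1.96·SD over B bootstrap replicates drawn
    multinomially from the coverage-adjusted bootstrap community.
    """
    _require_q0(q)
    if B < 2:
        raise InputError(f"B must be >= 2, got {B}")
    if list(m_grid) != sorted(m_grid):
        raise InputError("m_grid must be sorted ascending")
    rng = np.random.default_rng(seed)
    reps = _bootstrap_replicates(X, B, rng)
    boot = np.empty((B, len(m_grid)))
    for b, Xb in enumerate(reps):
        for j, m in enumerate(m_grid):
            boot[b, j] = richness_hat(Xb, int(m))
    sd = boot.std(axis=0, ddof=1)
    points = []
    for j, m in enumerate(m_grid):
        m = int(m)
        rich = richness_hat(X, m)
        cov = coverage_hat(X, m)
        regime = "interpolated" if m < X.n else ("observed" if m == X.n else "extrapolated")
        points.append(
            CurvePoint(
                m=m,
                coverage=cov,
                richness=rich,
                ci_lo=max(0.0, rich - Z_95 * sd[j]),
                ci_hi=rich + Z_95 * sd[j],
                regime=regime,
            )
        )
    return DiversityCurve(points=tuple(points), q=q, B=B, seed=seed)


def default_m_grid(X: AbundanceVector, extend: float = 2.0, knots: int = 40) -> list[int]:
    """Evenly spaced sample sizes from 1 up to ``extend``× the reference size."""
    m_max = max(int(round(extend * X.n)), X.n + 1)
    grid = np.unique(np.round(np.linspace(1, m_max, knots)).astype(int))
    if X.n not in grid:
        grid = np.unique(np.append(grid, X.n))
    return [int(m) for m in grid]


def invert_coverage(
    X: AbundanceVector,
    coverage_level: float,
    m_max: int | None = None,
    label: str = "catalogue",
) -> float:
    """Smallest (real-valued) sample size m whose estimated coverage reaches
    ``coverage_level``, interpolating linearly between adjacent integers."""
    if not 0.0 < coverage_level < 1.0:
        raise InputError("coverage_level must be in (0, 1)")
    if m_max is None:
        m_max = 2 * X.n
    c_max = coverage_hat(X, m_max)
    if c_max < coverage_level:
        raise CoverageUnreachableError(label, coverage_level, c_max)
    if coverage_hat(X, 1) >= coverage_level:
        return 1.0
    lo, hi = 1, m_max  # coverage(lo) < level <= coverage(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if coverage_hat(X, mid) >= coverage_level:
            hi = mid
        else:
            lo = mid
    c_lo, c_hi = coverage_hat(X, lo), coverage_hat(X, hi)
    if c_hi == c_lo:
        return float(hi)
    w = (coverage_level - c_lo) / (c_hi - c_lo)
    return lo + w


def richness_at_coverage(
    X: AbundanceVector,
    coverage_level: float,
    m_max: int | None = None,
    label: str = "catalogue",
) -> tuple[float, float]:
    """(m, richness) at the requested coverage level."""
    m = invert_coverage(X, coverage_level, m_max=m_max, label=label)
    return m, richness_hat(X, m)


def relative_diversity(
    X_a: AbundanceVector,
    X_b: AbundanceVector,
    coverage_level: float,
    B: int = 10,
    seed: int | None = None,
    m_max_factor: float = 2.0,
    q: int = 0,
) -> RelativeDiversity:
    """Richness ratio A/B at a common coverage level, with bootstrap CI.

    Replicates are paired: replicate b redraws both communities and re-inverts
    the coverage level on each before taking the ratio.  In a replicate where
    the level is not reachable within the extrapolation range the richness at
    the range end is used (the point estimate is never clamped).
    """
    _require_q0(q)
    if B < 2:
        raise InputError(f"B must be >= 2, got {B}")
    m_max_a = int(round(m_max_factor * X_a.n))
    m_max_b = int(round(m_max_factor * X_b.n))
    m_a, rich_a = richness_at_coverage(X_a, coverage_level, m_max_a, label="catalogue A")
    m_b, rich_b = richness_at_coverage(X_b, coverage_level, m_max_b, label="catalogue B")
    ratio = rich_a / rich_b

    rng = np.random.default_rng(seed)
    reps_a = _bootstrap_replicates(X_a, B, rng)
    reps_b = _bootstrap_replicates(X_b, B, rng)
    ratios = np.empty(B)
    for b in range(B):
        ratios[b] = _replicate_richness(reps_a[b], coverage_level, m_max_a) / _replicate_richness(
            reps_b[b], coverage_level, m_max_b
        )
    sd = float(ratios.std(ddof=1))
    return RelativeDiversity(
        ratio=float(ratio),
        ci_lo=max(0.0, ratio - Z_95 * sd),
        ci_hi=ratio + Z_95 * sd,
        coverage_level=coverage_level,
        m_a=m_a,
        m_b=m_b,
        richness_a=rich_a,
        richness_b=rich_b,
        B=B,
    )


def _replicate_richness(Xb: AbundanceVector, level: float, m_max: int) -> float:
    try:
        return richness_at_coverage(Xb, level, m_max)[1]
    except CoverageUnreachableError:
        return richness_hat(Xb, m_max)


def _require_q0(q: int) -> None:
    if q != 0:
        raise InputError(
            f"only Hill order q=0 (clonotype richness) is implemented, got q={q}"
        )
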