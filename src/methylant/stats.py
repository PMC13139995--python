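"""Core statistics shared by every pipeline stage.

The pipeline leans on four primitives: an exact binomial upper tail (the
per-site and per-gene methylation tests), Benjamini–Hochberg step-up
q-values, the Wilcoxon rank-sum test (island vs. background methylation,
expression by methylation class), and Pearson correlation with a
t-distributed p-value (cross-technology concordance, methylation vs.
expression).

The rank-sum test switches to exact enumeration of all rank assignments
when the combined sample size is small (``n1 + n2 <= 10``), so that
deterministic unit tests see exact small-sample p-values; larger samples
use the tie-corrected normal approximation with continuity correction,
matching R's ``wilcox.test`` conventions (the W statistic is the
Mann-Whitney U of the first sample).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .errors import ConfigError, DataError

__all__ = [
    "TestResult",
    "binomial_upper_tail",
    "binomial_lower_tail",
    "bh_adjust",
    "wilcoxon_rank_sum",
    "pearson_correlation",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``statistic`` is W for rank-sum tests and r for correlations; ``n1``
    / ``n2`` are the group sizes (``n2`` is None for one-sample
    quantities); ``method`` tags how the p-value was obtained.
    """

    statistic: float
    p_value: float
    n1: int
    n2: int | None
    method: str


def _check_kn(k, n) -> tuple[np.ndarray, np.ndarray]:
    k = np.asarray(k)
    n = np.asarray(n)
    if np.any(k < 0) or np.any(n < 0) or np.any(k > n):
        raise ConfigError("binomial tail requires 0 <= k <= n")
    return k, n


def binomial_upper_tail(k, n, p0):
    """P(X >= k) for X ~ Binomial(n, p0).

    Vectorised over ``k`` and ``n``. Exact (computed in log space by the
    regularised incomplete beta function) for any n this pipeline sees.
    ``k = 0`` gives 1 by convention; ``p0 = 0`` with ``k > 0`` gives an
    exact 0.
    """
    k, n = _check_kn(k, n)
    if not 0.0 <= p0 <= 1.0:
        raise ConfigError(f"p0 must be in [0, 1], got {p0}")
    out = _sps.binom.sf(k - 1, n, p0)
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def binomial_lower_tail(k, n, p0):
    """P(X <= k) for X ~ Binomial(n, p0); complements the upper tail.

    Accepts k = -1 (an empty lower tail) so that upper(k) + lower(k-1)
    always sums to 1.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    if np.any(k < -1) or np.any(n < 0) or np.any(k > n):
        raise ConfigError("binomial lower tail requires -1 <= k <= n")
    if not 0.0 <= p0 <= 1.0:
        raise ConfigError(f"p0 must be in [0, 1], got {p0}")
    out = _sps.binom.cdf(k, n, p0)
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with input.

    q_(i) = min over j with p_(j) >= p_(i) of m * p_(j) / rank(j),
    clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ConfigError("bh_adjust expects a 1-d array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ConfigError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _rank_with_ties(values: np.ndarray) -> np.ndarray:
    return _sps.rankdata(values, method="average")


def _exact_two_sided_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Enumerate all C(N, n1) assignments of the observed midranks."""
    n = ranks.size
    offset = n1 * (n1 + 1) / 2.0
    us = []
    for idx in itertools.combinations(range(n), n1):
        us.append(ranks[list(idx)].sum() - offset)
    us = np.asarray(us)
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_rank_sum(x, y, exact_max_n: int = 10) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Midranks are used for ties. For ``n1 + n2 <= exact_max_n`` the
    p-value is the exact two-sided tail from enumerating every rank
    assignment (2 * min(P(U<=u), P(U>=u)), capped at 1); otherwise the
    tie-corrected normal approximation with a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("wilcoxon_rank_sum requires non-empty groups")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _rank_with_ties(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0  # Mann-Whitney U of x (R's W)

    if n1 + n2 <= exact_max_n:
        p = _exact_two_sided_p(ranks, n1, u)
        return TestResult(u, p, n1, n2, "rank-sum/exact")

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # every value tied with every other
        return TestResult(u, 1.0, n1, n2, "rank-sum/normal")
    diff = u - mu
    z = (diff - np.sign(diff) * 0.5) / np.sqrt(var)
    p = float(min(1.0, 2.0 * _sps.norm.sf(abs(z))))
    return TestResult(u, p, n1, n2, "rank-sum/normal")


def pearson_correlation(x, y) -> TestResult:
    """Sample Pearson r with the t-based two-sided p-value.

    Requires at least 3 paired observations and non-constant inputs
    (r is undefined on a constant vector).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DataError("pearson_correlation requires equal-length vectors")
    if x.size < 3:
        raise DataError("pearson_correlation requires at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("pearson_correlation is undefined for constant input")
    r, p = _sps.pearsonr(x, y)
    return TestResult(float(r), float(p), int(x.size), None, "pearson/t")
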