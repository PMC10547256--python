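"""Exact small-sample statistical primitives used throughout the pipeline.

Every test downstream stages rely on (Fisher's exact test, one-tailed
binomial tails, Wilcoxon rank-sum, Spearman rank correlation, BH/FDR
adjustment, Shannon entropy) is implemented here from first principles so
that small-sample behaviour is exact and fully under package control.
p-value arithmetic is carried out in log space wherever underflow is
possible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "spearman_rho",
    "fisher_exact",
    "binomial_tail_ge",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "shannon_entropy",
    "ConstantInputError",
]


class ConstantInputError(ValueError):
    """Raised when a rank correlation is requested for a constant vector."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of counts; row 1 = group of interest, col 1 = outcome of interest."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or cell != int(cell):
                raise ValueError("cells must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero contingency table")


@dataclass(frozen=True)
class TestResult:
    """Statistic + p-value, with a flag for degenerate inputs."""

    statistic: float
    p: float
    flagged: bool = False
    note: str = ""


def _log_binom(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


# ---------------------------------------------------------------------------
# Spearman rank correlation


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman's rho on mid-ranks with a two-sided p-value.

    The p-value is exact (full permutation enumeration) for n <= 9 and a
    t-approximation otherwise.  A constant input vector has no defined rank
    correlation and raises :class:`ConstantInputError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("rank correlation undefined for constant input")
    rx = rankdata(x)  # mid-ranks for ties
    ry = rankdata(y)
    rho = _rho_from_ranks(rx, ry)
    if n <= 9:
        observed = abs(rho)
        hits = total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rho_from_ranks(rx, np.array(perm))) >= observed - 1e-12:
                hits += 1
        p = hits / total
    else:
        # t-approximation with n-2 degrees of freedom
        r = min(max(rho, -1.0), 1.0)
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1 - r * r))
            p = 2.0 * _student_t_sf(abs(t), n - 2)
    return TestResult(statistic=rho, p=min(p, 1.0))


def _student_t_sf(t: float, df: int) -> float:
    """Survival function of Student's t via the regularized incomplete beta."""
    from scipy.special import betainc

    x = df / (df + t * t)
    return 0.5 * betainc(df / 2.0, 0.5, x)


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_exact(table: ContingencyTable2x2, sided: str = "two") -> TestResult:
    """Fisher's exact test by hypergeometric enumeration over fixed margins.

    ``sided='greater'`` tests enrichment of cell *a* (row 1 associated with
    col 1); ``'two'`` sums the probabilities of all tables at most as likely
    as the observed one (probability-mass rule).  The odds ratio is the
    sample odds ratio ad/bc, reported as ``inf`` when bc = 0 with ad > 0 and
    flagged NaN when both products vanish.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if sided not in ("two", "greater", "less"):
        raise ValueError("sided must be 'two', 'greater' or 'less'")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        # a degenerate margin: the table carries no information
        odds = _sample_odds_ratio(a, b, c, d)
        return TestResult(statistic=odds, p=1.0, flagged=True, note="degenerate margin")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = _log_binom(n, c1)
    logp = np.array(
        [_log_binom(r1, k) + _log_binom(r2, c1 - k) - denom for k in range(lo, hi + 1)]
    )
    obs = logp[a - lo]
    if sided == "greater":
        p = float(np.exp(logsumexp(logp[a - lo :])))
    elif sided == "less":
        p = float(np.exp(logsumexp(logp[: a - lo + 1])))
    else:
        # include all tables with probability <= observed (small relative slack
        # for floating-point equality, matching reference implementations)
        keep = logp <= obs + 1e-7
        p = float(np.exp(logsumexp(logp[keep])))
    return TestResult(statistic=_sample_odds_ratio(a, b, c, d), p=min(p, 1.0))


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    ad, bc = a * d, b * c
    if bc == 0:
        return math.inf if ad > 0 else math.nan
    return ad / bc


# ---------------------------------------------------------------------------
# Binomial tail


def binomial_tail_ge(x: int, n: int, p0: float) -> float:
    """P(X >= x) for X ~ Binomial(n, p0), summed in log space."""
    if not (0 <= x <= n):
        raise ValueError("require 0 <= x <= n")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError("p0 must be in [0,1]")
    if x == 0:
        return 1.0
    if p0 == 0.0:
        return 0.0
    if p0 == 1.0:
        return 1.0
    lp, lq = math.log(p0), math.log1p(-p0)
    terms = [_log_binom(n, k) + k * lp + (n - k) * lq for k in range(x, n + 1)]
    return float(min(1.0, np.exp(logsumexp(terms))))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney)


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], sided: str = "two"
) -> TestResult:
    """Wilcoxon rank-sum test of the samples ``a`` versus ``b``.

    ``sided='less'`` tests the alternative that ``a`` tends to be smaller
    than ``b``; ``'greater'`` the reverse.  Exact enumeration over all
    assignments of the pooled values is used when the pooled size is <= 12,
    and a tie- and continuity-corrected normal approximation otherwise.
    When every pooled value is identical the test is vacuous: p = 1 with a
    warning flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be nonempty")
    if sided not in ("two", "greater", "less"):
        raise ValueError("sided must be 'two', 'greater' or 'less'")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return TestResult(statistic=math.nan, p=1.0, flagged=True, note="all values tied")
    ranks = rankdata(pooled)
    n1, n2 = a.size, b.size
    w_obs = float(ranks[:n1].sum())
    if n1 + n2 <= 12:
        # exact: enumerate which pooled positions belong to sample a
        sums = [
            float(ranks[list(idx)].sum())
            for idx in itertools.combinations(range(n1 + n2), n1)
        ]
        sums = np.array(sums)
        total = sums.size
        p_le = float(np.sum(sums <= w_obs + 1e-9)) / total
        p_ge = float(np.sum(sums >= w_obs - 1e-9)) / total
        if sided == "less":
            p = p_le
        elif sided == "greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mu = n1 * (n1 + n2 + 1) / 2.0
        # tie correction on the rank variance
        _, counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        sigma = math.sqrt(sigma2)
        if sided == "less":
            z = (w_obs - mu + 0.5) / sigma
            p = _norm_cdf(z)
        elif sided == "greater":
            z = (w_obs - mu - 0.5) / sigma
            p = 1.0 - _norm_cdf(z)
        else:
            z = (abs(w_obs - mu) - 0.5) / sigma
            p = 2.0 * (1.0 - _norm_cdf(z))
    return TestResult(statistic=w_obs, p=min(p, 1.0))


def _norm_cdf(z: float) -> float:
    return 0.5 * math.erfc(-z / math.sqrt(2.0))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values ("q-values").

    Output order matches input order; q is monotone in p, never below the
    raw p, and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Shannon entropy


def shannon_entropy(counts: Mapping[object, float], base: float = 2.0) -> float:
    """H = -sum f log_base f over categories with positive count."""
    vals = np.array([v for v in counts.values() if v > 0], dtype=float)
    if vals.size == 0:
        raise ValueError("entropy of empty counts is undefined")
    f = vals / vals.sum()
    return float(max(0.0, -(f * (np.log(f) / np.log(base))).sum()))
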