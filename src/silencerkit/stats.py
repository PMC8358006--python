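"""Statistical primitives used by all analysis stages.

The rank-sum test is authored here because the pipeline needs a documented
exact mode (full enumeration for small samples, with midrank ties) that it
can verify against brute force; tail probabilities for the hypergeometric
distribution come from scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "EnrichmentRecord",
    "mann_whitney",
    "rank_correlation",
    "hypergeometric_enrichment",
    "bh_fdr",
    "empirical_p",
]

EXACT_MW_MAX_N = 16  # total sample size at or below which MW is enumerated


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    k: int   # hits in set
    n: int   # set size
    K: int   # term size
    N: int   # universe size
    p_hyper: float
    enrichment_factor: float

    @property
    def passes(self) -> bool:
        """Default reporting gate: p < 0.01 and enrichment factor > 1.5."""
        return self.p_hyper < 0.01 and self.enrichment_factor > 1.5


def _midranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their midrank."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=np.float64)
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Mann-Whitney U (Wilcoxon rank-sum) test.

    Exact enumeration over all label arrangements when n1 + n2 <=
    ``EXACT_MW_MAX_N``; otherwise a normal approximation with tie and
    continuity corrections.  The statistic is U for ``x``.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative: {alternative}")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("mann_whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    if n1 + n2 <= EXACT_MW_MAX_N:
        # exact: enumerate all C(n1+n2, n1) choices of which pooled ranks
        # belong to x; U depends on ranks only, so ties are handled by the
        # shared midranks
        n = n1 + n2
        base = n1 * (n1 + 1) / 2.0
        us = np.array([
            sum(ranks[list(idx)]) - base for idx in combinations(range(n), n1)
        ])
        total = len(us)
        eps = 1e-9
        if alternative == "greater":
            p = np.sum(us >= u - eps) / total
        elif alternative == "less":
            p = np.sum(us <= u + eps) / total
        else:
            dev = abs(u - mu)
            p = np.sum(np.abs(us - mu) >= dev - eps) / total
        method = "mann-whitney-exact"
    else:
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            sd = math.sqrt(sigma2)
            if alternative == "greater":
                z = (u - mu - 0.5) / sd
                p = float(sps.norm.sf(z))
            elif alternative == "less":
                z = (u - mu + 0.5) / sd
                p = float(sps.norm.cdf(z))
            else:
                z = (abs(u - mu) - 0.5) / sd
                p = float(2.0 * sps.norm.sf(max(z, 0.0)))
        p = min(1.0, max(0.0, p))
        method = "mann-whitney-normal"
    return TestResult(statistic=float(u), p_value=float(p), method=method,
                      n1=n1, n2=n2)


def rank_correlation(
    x: Sequence[float], y: Sequence[float], method: str = "spearman"
) -> tuple[float, float]:
    """Spearman (midrank) or Pearson correlation with a t-approximation p."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("vector x is constant")
    if np.ptp(y) == 0:
        raise ValueError("vector y is constant")
    if method == "spearman":
        xv, yv = _midranks(x), _midranks(y)
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            raise ValueError("constant ranks after tie handling")
    elif method == "pearson":
        xv, yv = x, y
    else:
        raise ValueError(f"unknown method: {method}")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return r, min(1.0, p)


def hypergeometric_enrichment(
    k: int, n: int, K: int, N: int, term_id: str = ""
) -> EnrichmentRecord:
    """Upper-tail (cumulative) hypergeometric enrichment P(X >= k).

    ``k`` hits in a set of ``n``, for a term of size ``K`` in a universe of
    ``N``.  Enrichment factor is observed/expected = (k/n)/(K/N).
    """
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}")
    if n > N or K > N or n < 1 or K < 0 or N < 1:
        raise ValueError(f"inconsistent counts: n={n}, K={K}, N={N}")
    p = float(sps.hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
    p = min(1.0, max(0.0, p))
    ef = (k / n) / (K / N) if K > 0 else float("nan")
    return EnrichmentRecord(term_id=term_id, k=k, n=n, K=K, N=N,
                            p_hyper=p, enrichment_factor=ef)


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=np.float64)
    out[order] = adj
    return out.tolist()


def empirical_p(
    observed: float, null_draws: Sequence[float], tail: str = "greater"
) -> float:
    """Add-one empirical p-value: (1 + #extreme) / (1 + #draws); never 0."""
    draws = np.asarray(null_draws, dtype=np.float64)
    if draws.size == 0:
        raise ValueError("empirical_p requires at least one null draw")
    if tail == "greater":
        extreme = int(np.sum(draws >= observed))
    elif tail == "less":
        extreme = int(np.sum(draws <= observed))
    else:
        raise ValueError(f"unknown tail: {tail}")
    return (1 + extreme) / (1 + draws.size)
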