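"""Exact-test primitives shared across the pipeline.

The hypergeometric upper tail is evaluated in log space (gammaln +
log-sum-exp) so that enrichment p-values remain accurate far into the
tail (p ~ 1e-60 on gene-set-sized universes) where naive summation of
pmf terms underflows or cancels.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "log_hypergeom_pmf",
    "hypergeom_upper_tail",
    "fisher_enrichment",
    "bh_adjust",
]


def log_hypergeom_pmf(k, N, K, n):
    """log P(X = k) for X ~ Hypergeom(N, K, n) (k successes in n draws)."""
    k = np.asarray(k, dtype=float)
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - n + k + 1)
        + gammaln(n + 1) + gammaln(N - n + 1) - gammaln(N + 1)
    )


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact to ~1e-13 relative.

    Parameters are the universe size N, the number of marked items K,
    the draw size n and the observed overlap k.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric table: N={N}, K={K}, n={n}")
    k_lo = max(0, K + n - N)
    k_hi = min(K, n)
    if k <= k_lo:
        return 1.0
    if k > k_hi:
        return 0.0
    ks = np.arange(k, k_hi + 1)
    return float(min(1.0, np.exp(logsumexp(log_hypergeom_pmf(ks, N, K, n)))))


def fisher_enrichment(n11: int, n10: int, n01: int, n00: int) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test on a 2x2 table.

    Table layout: rows = in/out of set A, columns = in/out of set B;
    ``n11`` is the overlap. Returns ``(odds_ratio, p)`` where p is the
    hypergeometric upper-tail probability of an overlap >= n11 under
    fixed margins. The odds ratio uses the Haldane-Anscombe 0.5
    correction only when a cell is zero.
    """
    for v in (n11, n10, n01, n00):
        if v < 0:
            raise ValueError("negative cell count")
    N = n11 + n10 + n01 + n00
    if N == 0:
        raise ValueError("empty table")
    p = hypergeom_upper_tail(n11, N, n11 + n10, n11 + n01)
    if min(n11, n10, n01, n00) == 0:
        odds = ((n11 + 0.5) * (n00 + 0.5)) / ((n10 + 0.5) * (n01 + 0.5))
    else:
        odds = (n11 * n00) / (n10 * n01)
    return odds, p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (monotone, q >= p)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
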