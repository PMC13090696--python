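"""Small statistical primitives shared across modules.

The exact Wilcoxon rank-sum path enumerates the permutation distribution of
the rank sum with a subset-sum dynamic program over (possibly tied) ranks, so
small-sample marker p-values agree with brute-force enumeration to machine
precision. The asymptotic path is the usual normal approximation with tie
correction and continuity correction.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

#: per-group size at or below which the exact permutation distribution is used
EXACT_MAX_N = 25


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero (5 rounds up), as printed reports use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _exact_rank_sum_tails(ranks2: np.ndarray, n1: int, w2_obs: int) -> tuple[float, float]:
    """P(W <= w_obs) and P(W >= w_obs) for the rank sum of group 1.

    ``ranks2`` are doubled midranks (integers even with .5 ties); ``w2_obs``
    is the doubled observed rank sum. Counts subsets by a DP over
    (#chosen, rank-sum): table[k, s] = number of k-subsets with doubled sum s.
    """
    total = int(ranks2.sum())
    table = np.zeros((n1 + 1, total + 1), dtype=float)
    table[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        # iterate k downward so each rank is used at most once
        for k in range(n1, 0, -1):
            table[k, r:] += table[k - 1, : total + 1 - r]
    dist = table[n1]
    n_subsets = dist.sum()
    p_le = dist[: w2_obs + 1].sum() / n_subsets
    p_ge = dist[w2_obs:].sum() / n_subsets
    return p_le, p_ge


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of ``x`` vs ``y``.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``x``. Exact
    enumeration (tie-aware) is used when both groups have <= 25 observations,
    otherwise the normal approximation with tie correction and continuity
    correction. The two-sided exact p doubles the smaller tail, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = ranks[:n1].sum()
    u = w - n1 * (n1 + 1) / 2.0

    if max(n1, n2) <= EXACT_MAX_N:
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w))
        p_le, p_ge = _exact_rank_sum_tails(ranks2, n1, w2)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u, p

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:  # all values identical
        return u, 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    return u, min(1.0, 2.0 * stats.norm.sf(z))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out
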