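"""Rank statistics shared by the benchmark and analysis modules.

Exact one-sided p-values are computed by enumeration for small samples
(permutation distribution for the Mann-Whitney U, sign-flip distribution for
the Wilcoxon signed-rank); larger samples fall back to the normal
approximation with tie correction and continuity correction.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["auroc", "mann_whitney_u", "wilcoxon_signed_rank"]

_EXACT_MW_LIMIT = 12   # exact enumeration when n + m <= this
_EXACT_WILCOXON_LIMIT = 15


def auroc(y_true, scores) -> float:
    """Area under the ROC curve by the rank statistic; ties contribute 1/2."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    pos = y_true == 1
    n_pos = int(pos.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined for a degenerate label")
    ranks = rankdata(scores)
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample ``a``: #pairs with a > b plus half the ties."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_u(a, b, alternative: str = "greater",
                   method: str = "auto") -> tuple[float, float]:
    """One-sided Mann-Whitney U test; returns (U of sample a, p-value).

    Exact by enumerating all pooled-value assignments when n + m is small,
    otherwise normal approximation with tie and continuity correction.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if method not in ("auto", "exact", "normal"):
        raise ValueError("method must be auto, exact or normal")
    n, m = len(a), len(b)
    u_obs = _u_statistic(a, b)
    use_exact = method == "exact" or (method == "auto" and n + m <= _EXACT_MW_LIMIT)
    if use_exact:
        pooled = np.concatenate([a, b])
        idx = np.arange(n + m)
        total = 0
        hits = 0
        for chosen in combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(chosen)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if alternative == "greater":
                hits += u >= u_obs
            else:
                hits += u <= u_obs
        return u_obs, hits / total
    # normal approximation with tie correction
    pooled = np.concatenate([a, b])
    nn = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts)
    mu = n * m / 2.0
    sigma2 = n * m / 12.0 * ((nn + 1) - tie_term / (nn * (nn - 1)))
    sigma = np.sqrt(sigma2)
    if sigma == 0:
        return u_obs, 1.0
    if alternative == "greater":
        z = (u_obs - mu - 0.5) / sigma
        return u_obs, float(norm.sf(z))
    z = (u_obs - mu + 0.5) / sigma
    return u_obs, float(norm.cdf(z))


def wilcoxon_signed_rank(x, mu: float = 0.0, alternative: str = "greater",
                         method: str = "auto") -> tuple[float, float]:
    """One-sided Wilcoxon signed-rank test of ``x`` against location ``mu``.

    Zero differences are dropped; returns (W+ statistic, p-value). Exact by
    enumerating all sign assignments for small n.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) == 0:
        raise ValueError("sample must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    d = x - mu
    d = d[d != 0]
    if len(d) == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    if method not in ("auto", "exact", "normal"):
        raise ValueError("method must be auto, exact or normal")
    w_obs = float(ranks[d > 0].sum())
    n = len(d)
    if method == "exact" or (method == "auto" and n <= _EXACT_WILCOXON_LIMIT):
        total = 2 ** n
        signs = (np.arange(total)[:, None] >> np.arange(n)) & 1
        w_all = signs @ ranks
        if alternative == "greater":
            return w_obs, float(np.mean(w_all >= w_obs))
        return w_obs, float(np.mean(w_all <= w_obs))
    mu_w = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts ** 3 - counts) / 48.0
    sigma = np.sqrt(sigma2)
    if alternative == "greater":
        z = (w_obs - mu_w - 0.5) / sigma
        return w_obs, float(norm.sf(z))
    z = (w_obs - mu_w + 0.5) / sigma
    return w_obs, float(norm.cdf(z))
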