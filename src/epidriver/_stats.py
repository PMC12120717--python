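"""Shared statistical primitives: Spearman correlation, BH adjustment,
upper-tail hypergeometric probability, paired Wilcoxon p-values."""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

EXACT_SPEARMAN_MAX_N = 9


def spearman(x, y, exact_max_n: int = EXACT_SPEARMAN_MAX_N) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The two-sided p-value uses the t-approximation for n > ``exact_max_n``
    and exhaustive permutation enumeration for small n.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValidationError("spearman requires two vectors of equal length >= 3")
    rho, p = stats.spearmanr(x, y)
    if n <= exact_max_n:
        p = _exact_spearman_p(x, y, rho)
    return float(rho), float(p)


def _exact_spearman_p(x, y, rho_obs: float) -> float:
    """Two-sided p by enumerating all pairings of the rank vectors."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    denom_x = np.sqrt((rx**2).sum())
    ry_c = ry - ry.mean()
    denom_y = np.sqrt((ry_c**2).sum())
    if denom_x == 0 or denom_y == 0:
        return 1.0
    count = 0
    total = 0
    for perm in itertools.permutations(ry_c):
        r = np.dot(rx, perm) / (denom_x * denom_y)
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_upper(k: int, n_universe: int, n_successes: int, n_draws: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(universe, successes, draws)."""
    return float(stats.hypergeom.sf(k - 1, n_universe, n_successes, n_draws))


def paired_wilcoxon_p(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided paired Wilcoxon signed-rank p per row of (n_tests, n_pairs).

    Rows whose differences are all zero (or all NaN) get p = 1.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    d = x - y
    p = np.ones(d.shape[0])
    for i in range(d.shape[0]):
        di = d[i]
        di = di[~np.isnan(di)]
        if di.size == 0 or np.all(di == 0):
            continue
        try:
            p[i] = stats.wilcoxon(di, alternative="two-sided").pvalue
        except ValueError:
            p[i] = 1.0
    return p
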