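"""Shared rank-correlation utilities.

Spearman correlations drive the supervised feature screens, so they are
computed in vectorized form (one response against a feature matrix).
P-values use the large-sample t approximation with tie-corrected ranks,
except at very small n (<= 9, no ties) where the exact permutation null of
rho is enumerated once per n and cached; the screens must be reproducible
at leave-one-patient-out training sizes.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

import numpy as np
from scipy import stats

EXACT_N_MAX = 9


def _rank(a: np.ndarray, axis: int = 0) -> np.ndarray:
    return stats.rankdata(a, axis=axis)


@lru_cache(maxsize=None)
def _exact_rho_null(n: int) -> np.ndarray:
    """Sorted null distribution of Spearman rho for untied samples of size n."""
    base = np.arange(1, n + 1, dtype=float)
    base = (base - base.mean()) / base.std()
    perms = np.array(list(permutations(range(n))), dtype=np.intp)
    rhos = (base[perms] * base).mean(axis=1)
    rhos.sort()
    return rhos


def _exact_p_two_sided(rho: float, n: int) -> float:
    null = _exact_rho_null(n)
    # two-sided: fraction of |null| >= |rho| (with numerical slack)
    return float(np.mean(np.abs(null) >= abs(rho) - 1e-12))


def spearman_vector(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p for ``y`` against each column of ``X``.

    Parameters
    ----------
    y : (n,) response values
    X : (n, m) feature matrix

    Returns
    -------
    rho, p : arrays of length m; NaN where a column (or y) is constant.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and X must have the same number of rows")
    n = y.shape[0]
    ry = _rank(y)
    rX = _rank(X, axis=0)
    ry_c = ry - ry.mean()
    rX_c = rX - rX.mean(axis=0)
    denom = np.sqrt((ry_c**2).sum() * (rX_c**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, rX_c.T @ ry_c / np.where(denom > 0, denom, 1.0), np.nan)
    rho = np.clip(rho, -1.0, 1.0)

    p = np.full_like(rho, np.nan)
    ok = np.isfinite(rho)
    y_tied = np.unique(y).size < n
    if n <= EXACT_N_MAX and not y_tied:
        for j in np.nonzero(ok)[0]:
            if np.unique(X[:, j]).size == n:
                p[j] = _exact_p_two_sided(rho[j], n)
            else:
                p[j] = _t_approx_p(rho[j], n)
    elif n > 2:
        p[ok] = _t_approx_p(rho[ok], n)
    return rho, p


def _t_approx_p(rho, n: int):
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.clip(1.0 - rho**2, 1e-300, None))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided p for a single pair of vectors."""
    rho, p = spearman_vector(np.asarray(y, float), np.asarray(x, float).reshape(-1, 1))
    return float(rho[0]), float(p[0])


def spearman_corr_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlation matrix of the columns of X."""
    rX = _rank(np.asarray(X, dtype=float), axis=0)
    rX = rX - rX.mean(axis=0)
    sd = rX.std(axis=0)
    sd[sd == 0] = np.nan
    C = (rX.T @ rX) / X.shape[0]
    C = C / np.outer(sd, sd)
    return np.clip(C, -1.0, 1.0)
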