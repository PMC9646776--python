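"""Statistical utilities: autocorrelation-corrected correlation, scaling,
smoothing, a standardised-PCA index, and Euclidean average-linkage clustering.

The correlation correction follows the Pyper–Peterman effective-degrees-of-
freedom approach for serially correlated series:

    1/N* = 1/N + (2/N) * sum_j rho_xx(j) rho_yy(j)

with plain sample autocorrelations over lags j = 1 .. floor(N/5); the sum is
truncated at the first negative cross-product so the correction can only
reduce the effective sample size. Significance uses a two-sided t-test with
N* - 2 (possibly fractional) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist


@dataclass(frozen=True)
class CorrelationResult:
    sigma: float
    n: int
    n_eff: float
    p_acf: float
    p_raw: float


def _sample_acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = x - x.mean()
    denom = float(np.dot(x, x))
    return np.array([np.dot(x[:-j], x[j:]) / denom for j in range(1, max_lag + 1)])


def corrected_correlation(x, y, max_lag: int | None = None) -> CorrelationResult:
    """Pearson correlation with autocorrelation-corrected significance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and equal length")
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance series")
    sigma, p_raw = sps.pearsonr(x, y)
    if max_lag is None:
        max_lag = n // 5
    ax = _sample_acf(x, max_lag)
    ay = _sample_acf(y, max_lag)
    s = 0.0
    for j in range(max_lag):
        prod = ax[j] * ay[j]
        if prod < 0:
            break
        s += prod
    inv_neff = 1.0 / n + (2.0 / n) * s
    n_eff = min(float(n), 1.0 / inv_neff)
    df = n_eff - 2.0
    if df <= 0:
        p_acf = 1.0
    else:
        t = abs(sigma) * np.sqrt(df / max(1e-300, 1.0 - sigma**2))
        p_acf = 2.0 * sps.t.sf(t, df)
    p_acf = min(1.0, max(p_acf, p_raw))
    return CorrelationResult(sigma=float(sigma), n=n, n_eff=n_eff,
                             p_acf=float(p_acf), p_raw=float(p_raw))


def minmax_standardise(series, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Affine map of [min, max] of the series onto [lo, hi]."""
    s = np.asarray(series, dtype=float)
    rng = np.nanmax(s) - np.nanmin(s)
    if rng == 0:
        raise ValueError("constant series cannot be min-max standardised")
    return lo + (s - np.nanmin(s)) * (hi - lo) / rng


def moving_average(series, order: int = 1) -> np.ndarray:
    """Centred simple moving average of window 2*order + 1.

    Order 1 is the 3-point window; the window truncates at the series ends.
    Order 0 is the identity.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    s = np.asarray(series, dtype=float)
    if order == 0:
        return s.copy()
    n = len(s)
    out = np.empty(n)
    for i in range(n):
        out[i] = s[max(0, i - order): min(n, i + order + 1)].mean()
    return out


@dataclass(frozen=True)
class PCAIndexResult:
    scores: np.ndarray
    loadings: np.ndarray
    explained: np.ndarray


def standardised_pca_index(table, return_full: bool = False):
    """First principal component of column-standardised indicators.

    Columns are z-scored, the correlation matrix is eigen-decomposed, and
    PC1 scores are returned with the sign fixed so the first column's
    loading is non-negative.
    """
    m = np.asarray(table, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-d table with at least two indicators")
    if np.isnan(m).any():
        raise ValueError("missing values must be imputed before the PCA")
    sd = m.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise ValueError("rank-0 table")
    if np.any(sd == 0):
        raise ValueError("constant indicator column")
    z = (m - m.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    v1 = evecs[:, 0]
    if v1[0] < 0:
        v1 = -v1
    scores = z @ v1
    if return_full:
        return PCAIndexResult(scores=scores, loadings=v1,
                              explained=evals / evals.sum())
    return scores


def euclidean_upgma(matrix, k: int | None = None):
    """Average-linkage (UPGMA) clustering on Euclidean distances.

    Returns the scipy linkage matrix, or the flat partition labels when
    ``k`` is given.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim == 1:
        m = m[:, None]
    if m.shape[0] < 2:
        raise ValueError("need at least two items")
    z = linkage(pdist(m, metric="euclidean"), method="average")
    if k is None:
        return z
    if not (1 <= k <= m.shape[0]):
        raise ValueError("k out of range")
    return fcluster(z, t=k, criterion="maxclust")
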