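"""Shared vectorised least-squares helpers for the association scans.

All scans reduce to testing a single added regressor against a fixed
covariate block, so the Frisch–Waugh residualisation trick gives exact
partial F statistics for thousands of markers at once.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def residualise(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of y (vector or n x m matrix) on covariate block C (n x q)."""
    Q, _ = np.linalg.qr(C)
    return y - Q @ (Q.T @ y)


def partial_f_scan(
    y: np.ndarray, X: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Partial F test of each column of X added to the model y ~ C.

    Parameters
    ----------
    y : (n,) response
    X : (n, m) candidate regressors
    C : (n, q) covariate block, must include an intercept column

    Returns
    -------
    p_values, effects (slope of each x given C), r2 (share of total
    centred SS explained by adding x), df_resid
    """
    n = y.shape[0]
    q = np.linalg.matrix_rank(C)
    df = n - q - 1
    if df < 1:
        raise ValueError(f"not enough residual degrees of freedom (n={n}, q={q})")
    y_r = residualise(y, C)
    X_r = residualise(X, C)
    sse0 = float(y_r @ y_r)
    xtx = np.einsum("ij,ij->j", X_r, X_r)
    xty = X_r.T @ y_r
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(xtx > 0, xty / np.where(xtx > 0, xtx, 1.0), np.nan)
        ss_gain = np.where(xtx > 0, xty**2 / np.where(xtx > 0, xtx, 1.0), 0.0)
        sse1 = sse0 - ss_gain
        f = np.where(sse1 > 0, ss_gain / (sse1 / df), np.inf)
    p = stats.f.sf(f, 1, df)
    # markers collinear with the covariates carry no information
    p = np.where(xtx > 1e-12, p, np.nan)
    beta = np.where(xtx > 1e-12, beta, np.nan)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = ss_gain / sst if sst > 0 else np.zeros_like(ss_gain)
    return p, beta, r2, np.full(X.shape[1], df)


def rss(y: np.ndarray, C: np.ndarray) -> float:
    """Residual sum of squares of y on the column space of C."""
    r = residualise(y, C)
    return float(r @ r)
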