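"""Small, fast per-window regression solvers.

The Monte-Carlo validation fits on the order of a million tiny univariate
models (tens of observations, one predictor), so the solvers here are
vectorised across exposures: all M logistic models sharing the same outcome
vector are advanced through Newton-Raphson together.  Agreement with
statsmodels is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

_ETA_CLIP = 30.0


def logistic_profile(
    y: np.ndarray,
    X: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit M univariate logistic models logit(y) = b0 + b1*x_m jointly.

    Parameters
    ----------
    y : (n,) array of 0/1 outcomes.
    X : (n, M) array; column m is the single predictor of model m.
    ridge : L2 penalty on the slope (the intercept is never penalized;
        0 = plain MLE).

    Returns
    -------
    beta0, beta1 : (M,) intercepts and slopes.
    converged : (M,) boolean mask (gradient below ``tol``).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, M = X.shape
    b0 = np.zeros(M)
    b1 = np.zeros(M)
    yc = y[:, None]
    for _ in range(max_iter):
        eta = np.clip(b0 + X * b1, -_ETA_CLIP, _ETA_CLIP)
        p = expit(eta)
        r = yc - p
        g0 = r.sum(axis=0)
        g1 = (X * r).sum(axis=0) - ridge * b1
        if max(np.abs(g0).max(), np.abs(g1).max()) < tol:
            break
        w = p * (1.0 - p)
        a = w.sum(axis=0)
        bq = (w * X).sum(axis=0)
        c = (w * X * X).sum(axis=0) + ridge
        det = a * c - bq * bq
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        db0 = (c * g0 - bq * g1) / det
        db1 = (a * g1 - bq * g0) / det
        # damp very large Newton steps to avoid overshooting on near-separation
        step = np.maximum(1.0, np.maximum(np.abs(db0), np.abs(db1)) / 5.0)
        b0 += db0 / step
        b1 += db1 / step
    eta = np.clip(b0 + X * b1, -_ETA_CLIP, _ETA_CLIP)
    p = expit(eta)
    g0 = np.abs((yc - p).sum(axis=0))
    g1 = np.abs((X * (yc - p)).sum(axis=0) - ridge * b1)
    converged = np.maximum(g0, g1) < max(tol, 1e-5)
    return b0, b1, converged


def logistic_fit(
    y: np.ndarray,
    D: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> tuple[np.ndarray, bool]:
    """Newton-Raphson logistic fit with design matrix ``D`` (intercept first).

    Used for the confounder-adjusted path; the intercept (column 0) is not
    penalized.  Returns (beta, converged).
    """
    y = np.asarray(y, dtype=float)
    D = np.asarray(D, dtype=float)
    pen = np.full(D.shape[1], ridge)
    pen[0] = 0.0
    beta = np.zeros(D.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = np.clip(D @ beta, -_ETA_CLIP, _ETA_CLIP)
        p = expit(eta)
        g = D.T @ (y - p) - pen * beta
        if np.abs(g).max() < tol:
            converged = True
            break
        w = p * (1.0 - p)
        H = (D * w[:, None]).T @ D + np.diag(pen)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        norm = np.abs(step).max()
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
    else:
        eta = np.clip(D @ beta, -_ETA_CLIP, _ETA_CLIP)
        converged = bool(np.abs(D.T @ (y - expit(eta)) - pen * beta).max() < 1e-5)
    return beta, converged


def linear_slopes(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS slopes of y on each column of X (with intercept), vectorised."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc * xc).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sxx > 0, (xc * yc[:, None]).sum(axis=0) / sxx, np.nan)


def linear_fit(y: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Least-squares coefficients for design ``D`` (includes intercept)."""
    beta, *_ = np.linalg.lstsq(np.asarray(D, float), np.asarray(y, float), rcond=None)
    return beta
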