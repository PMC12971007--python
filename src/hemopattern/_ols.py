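"""Minimal ordinary-least-squares core used by the response-surface fits.

Classical (homoskedastic) coefficient covariance, QR-based solve. Kept
separate so Monte-Carlo tests can call it in tight loops without the
overhead of a full model object.
"""

from __future__ import annotations

import numpy as np


class RankDeficiencyError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; carries the offending column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


def check_full_rank(X: np.ndarray, names=None) -> None:
    """Raise :class:`RankDeficiencyError` naming collinear columns, if any."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank >= p:
        return
    if names is None:
        names = [f"x{j}" for j in range(p)]
    # Columns loading on near-null right-singular vectors are the culprits.
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(n, p) * np.finfo(float).eps
    null_space = vt[s < tol] if np.any(s < tol) else vt[-(p - rank):]
    loading = np.abs(null_space).max(axis=0)
    bad = [names[j] for j in np.nonzero(loading > 1e-8)[0]]
    raise RankDeficiencyError(bad or names)


def ols(X: np.ndarray, y: np.ndarray, names=None):
    """OLS fit returning ``(beta, cov_beta, residuals, df_resid)``.

    ``cov_beta`` is the classical estimate ``sigma^2 (X'X)^-1`` with
    ``sigma^2 = RSS / (n - p)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    check_full_rank(X, names)
    q, r = np.linalg.qr(X)
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    rinv = np.linalg.inv(r)
    cov = sigma2 * (rinv @ rinv.T)
    return beta, cov, resid, df
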