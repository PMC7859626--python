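"""Vectorized logistic regression (Newton/IRLS) batched across genes.

Per-gene likelihood-ratio screens over ~13k genes need thousands of small
logistic fits; these run them as one batched Newton iteration with a
(G, p, p) solve per step.  Separation / non-convergence falls back to a
small ridge penalty and is flagged per gene.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

MAX_ABS_BETA = 30.0


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # log p(y | eta) summed over samples; stable via logaddexp
    return (y * eta - np.logaddexp(0.0, eta)).sum(axis=-1)


def fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 0.0, max_iter: int = 60,
                 tol: float = 1e-10) -> tuple[np.ndarray, float, bool]:
    """Single ML (or ridge-penalized) logistic fit.

    Returns (beta, unpenalized log-likelihood, converged).
    """
    beta, ll, conv = batched_logistic(X[None, :, :], y, ridge=ridge,
                                      max_iter=max_iter, tol=tol)
    return beta[0], float(ll[0]), bool(conv[0])


def batched_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
                     max_iter: int = 60, tol: float = 1e-10
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Newton fits for G designs at once.

    Parameters
    ----------
    X : (G, n, p) stacked design matrices (intercept included by caller).
    y : (n,) binary outcome shared across designs.
    ridge : L2 penalty (not applied to the reported log-likelihood).

    Returns (beta (G,p), loglik (G,), converged (G,)).
    """
    G, n, p = X.shape
    beta = np.zeros((G, p))
    eye = np.eye(p)
    converged = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        eta = np.einsum("gnp,gp->gn", X, beta)
        mu = _sigmoid(eta)
        grad = np.einsum("gnp,gn->gp", X, y[None, :] - mu) - ridge * beta
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        hess = np.einsum("gnp,gn,gnq->gpq", X, w, X) + (ridge + 1e-12) * eye
        try:
            step = np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.einsum("gpq,gq->gp", np.linalg.pinv(hess), grad)
        # damp huge steps (separation drives |beta| -> inf)
        norms = np.linalg.norm(step, axis=1, keepdims=True)
        step = np.where(norms > 5.0, step * (5.0 / norms), step)
        beta = beta + step
        converged = np.abs(grad).max(axis=1) < tol * n
        if converged.all():
            break
    np.clip(beta, -MAX_ABS_BETA, MAX_ABS_BETA, out=beta)
    eta = np.einsum("gnp,gp->gn", X, beta)
    return beta, _loglik(eta, y), converged


def batched_feature_lrt(features: np.ndarray, y: np.ndarray,
                        covariates: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Likelihood-ratio test of each feature row added to the covariate model.

    Null: y ~ 1 (+ covariates).  Full: y ~ 1 (+ covariates) + feature_g.
    Features are standardized internally for numerical stability (the LRT is
    invariant to affine rescaling of a column).

    Returns (lrt_stat (G,), p_value (G,), penalized_flag (G,)).
    """
    features = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    G, n = features.shape
    cov_cols = [np.ones(n)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == n and cov.shape[1] != n:
            cov = cov.T
        for row in cov:
            cov_cols.append((row - row.mean()) / (row.std() or 1.0))
    X0 = np.column_stack(cov_cols)
    _, ll0, conv0 = batched_logistic(X0[None, :, :], y)
    if not conv0[0]:
        _, ll0, _ = batched_logistic(X0[None, :, :], y, ridge=1e-3)
    scale = features.std(axis=1)
    scale[scale == 0] = 1.0
    feats = (features - features.mean(axis=1, keepdims=True)) / scale[:, None]
    p = X0.shape[1] + 1
    X = np.empty((G, n, p))
    X[:, :, :-1] = X0[None, :, :]
    X[:, :, -1] = feats
    beta, ll1, conv = batched_logistic(X, y)
    # |beta| >= 10 on standardized features is a separation signature
    penalized = ~conv | (np.abs(beta).max(axis=1) >= 10.0)
    if penalized.any():
        idx = np.where(penalized)[0]
        beta_r, ll_r, _ = batched_logistic(X[idx], y, ridge=1e-3)
        ll1 = ll1.copy()
        ll1[idx] = ll_r
    stat = np.maximum(2.0 * (ll1 - ll0[0]), 0.0)
    pvals = stats.chi2.sf(stat, df=1)
    return stat, pvals, penalized
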