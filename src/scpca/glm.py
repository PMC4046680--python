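"""Lightweight logistic regression for the supervised association layer.

The permutation pipeline needs on the order of 1e5 two-parameter logistic
fits (per-SNP screening and score-on-trait Wald tests), so these are
implemented as vectorized IRLS with a Firth (Jeffreys-penalized) fallback for
separated data.  Estimates agree with a full ML fit to high precision; the
test suite cross-checks them against statsmodels.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from . import _kernels

__all__ = ["logistic_wald", "wald_t_fast", "per_snp_pvalues", "firth_logistic"]

_ETA_CLIP = 30.0
_SEP_BETA = 15.0  # |slope| beyond this is treated as (quasi-)separation


def wald_t_fast(x: np.ndarray, y: np.ndarray) -> float:
    """Wald t of y ~ 1 + x via a compiled IRLS (Firth fallback on
    separation); the pipeline's hot path."""
    x = np.ascontiguousarray(x, dtype=float)
    if np.ptp(x) == 0:
        return 0.0
    t, ok = _kernels.wald_t(x, y, 40, 1e-10)
    if ok:
        return float(t)
    b1, se1 = firth_logistic(x, y)
    return b1 / se1 if se1 > 0 else 0.0


def logistic_wald(x: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-12):
    """ML logistic fit of y on (1, x); returns (beta1, se1, t, converged).

    On separation or non-convergence the fit falls back to Firth's penalized
    likelihood, which keeps the Wald statistic finite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0:
        return 0.0, np.inf, 0.0, True
    b0, b1 = _init_intercept(y), 0.0
    converged = False
    for _ in range(max_iter):
        eta = np.clip(b0 + b1 * x, -_ETA_CLIP, _ETA_CLIP)
        p = expit(eta)
        w = p * (1.0 - p)
        r = y - p
        g0, g1 = r.sum(), (r * x).sum()
        s00, s01, s11 = w.sum(), (w * x).sum(), (w * x * x).sum()
        det = s00 * s11 - s01 * s01
        if det <= 1e-300:
            break
        d0 = (s11 * g0 - s01 * g1) / det
        d1 = (s00 * g1 - s01 * g0) / det
        b0 += d0
        b1 += d1
        if abs(d0) < tol and abs(d1) < tol:
            converged = True
            break
    if not converged or abs(b1) > _SEP_BETA:
        b1, se1 = firth_logistic(x, y)
        t = b1 / se1 if se1 > 0 else 0.0
        return b1, se1, t, False
    eta = np.clip(b0 + b1 * x, -_ETA_CLIP, _ETA_CLIP)
    w = expit(eta) * (1.0 - expit(eta))
    s00, s01, s11 = w.sum(), (w * x).sum(), (w * x * x).sum()
    det = s00 * s11 - s01 * s01
    se1 = np.sqrt(s00 / det)
    t = b1 / se1
    return b1, se1, t, True


def firth_logistic(x: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """Firth penalized logistic fit of y on (1, x); returns (beta1, se1).

    The Jeffreys-prior score correction replaces y with y + h (1/2 - p) where
    h are the hat-matrix diagonals, which yields finite estimates even under
    complete separation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.array([_init_intercept(y), 0.0])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        p = expit(eta)
        w = p * (1.0 - p)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        ystar = y + h * (0.5 - p)
        score = X.T @ (ystar - p)
        delta = info_inv @ score
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            break
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    w = expit(eta) * (1.0 - expit(eta))
    info = (X.T * w) @ X
    se1 = float(np.sqrt(np.linalg.inv(info)[1, 1]))
    return float(beta[1]), se1


def _init_intercept(y: np.ndarray) -> float:
    m = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    return float(np.log(m / (1 - m)))


def per_snp_pvalues(G, y) -> np.ndarray:
    """Two-sided Wald p-value of each SNP's slope in y ~ 1 + genotype.

    Genotypes enter numerically (0/1/2 minor-allele counts).  Constant
    columns get p = 1.  SNPs whose joint IRLS does not converge are refit
    individually (Firth on separation).
    """
    values = G.values if hasattr(G, "values") else np.asarray(G)
    X = np.asarray(values, dtype=float)
    yv = np.asarray(y.y if hasattr(y, "y") else y, dtype=float)
    n, d = X.shape
    pvals = np.ones(d)
    variable = np.ptp(X, axis=0) > 0
    if not variable.any():
        return pvals
    Xv = X[:, variable]
    m = Xv.shape[1]
    b0 = np.full(m, _init_intercept(yv))
    b1 = np.zeros(m)
    active = np.ones(m, dtype=bool)
    for _ in range(50):
        eta = np.clip(b0 + b1 * Xv, -_ETA_CLIP, _ETA_CLIP)
        p = expit(eta)
        w = p * (1.0 - p)
        r = yv[:, None] - p
        g0 = r.sum(axis=0)
        g1 = (r * Xv).sum(axis=0)
        s00 = w.sum(axis=0)
        s01 = (w * Xv).sum(axis=0)
        s11 = (w * Xv * Xv).sum(axis=0)
        det = np.maximum(s00 * s11 - s01 * s01, 1e-300)
        d0 = (s11 * g0 - s01 * g1) / det
        d1 = (s00 * g1 - s01 * g0) / det
        b0 = b0 + np.where(active, d0, 0.0)
        b1 = b1 + np.where(active, d1, 0.0)
        active = (np.abs(d0) > 1e-12) | (np.abs(d1) > 1e-12)
        if not active.any():
            break
    eta = np.clip(b0 + b1 * Xv, -_ETA_CLIP, _ETA_CLIP)
    p = expit(eta)
    w = p * (1.0 - p)
    s00 = w.sum(axis=0)
    s01 = (w * Xv).sum(axis=0)
    s11 = (w * Xv * Xv).sum(axis=0)
    det = np.maximum(s00 * s11 - s01 * s01, 1e-300)
    se1 = np.sqrt(s00 / det)
    t = b1 / se1
    pv = 2.0 * norm.sf(np.abs(t))
    # refit problematic columns one at a time (separation / non-convergence)
    bad = active | (np.abs(b1) > _SEP_BETA) | ~np.isfinite(pv)
    for j in np.flatnonzero(bad):
        _, _, tj, _ = logistic_wald(Xv[:, j], yv)
        pv[j] = 2.0 * norm.sf(abs(tj))
    pvals[variable] = pv
    return pvals
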