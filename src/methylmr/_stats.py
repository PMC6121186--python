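"""Shared numerics: vectorised simple regression, clamped p-values, and the
Gaussian-copula machinery used to control LD between simulated dosages."""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats

# Smallest positive subnormal double; p-values are clamped here so that a
# "numerically perfect" association still satisfies p in (0, 1].
MIN_P = 5e-324


class InfeasibleLDError(ValueError):
    """Raised when a requested LD target cannot be realised by the copula."""


def normal_p(z: np.ndarray | float) -> np.ndarray | float:
    """Two-sided p-value from a standard-normal z, clamped into (0, 1]."""
    p = 2.0 * special.ndtr(-np.abs(np.asarray(z, dtype=float)))
    return np.maximum(p, MIN_P)


def t_p(t: np.ndarray | float, df: int) -> np.ndarray | float:
    """Two-sided p-value from a t statistic with `df` degrees of freedom."""
    p = 2.0 * stats.t.sf(np.abs(np.asarray(t, dtype=float)), df)
    return np.maximum(p, MIN_P)


def simple_ols(X: np.ndarray, y: np.ndarray):
    """Simple linear regression of ``y`` on each row of ``X`` separately.

    Parameters
    ----------
    X : (m, n) array — one predictor per row, n observations.
    y : (n,) array.

    Returns
    -------
    beta, se, tstat, p : (m,) arrays. p is two-sided from t with n-2 df.
    Rows with zero predictor variance yield NaN estimates; callers are
    expected to filter those out beforehand.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if X.ndim == 1:
        X = X[None, :]
    if n < 3:
        raise ValueError("need at least 3 observations for a t test with n-2 df")
    xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->i", xc, xc)
    sxy = xc @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = np.maximum(syy - beta * sxy, 0.0)
        s2 = rss / (n - 2)
        se = np.sqrt(s2 / sxx)
        tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.sign(beta) * np.inf)
    p = t_p(tstat, n - 2)
    return beta, se, tstat, p


def _owens_t_bvn(h, k, rho):
    # Owen (1956): P(Z1<=h, Z2<=k) for standard bivariate normal.
    h = np.where(h == 0.0, 1e-13, h)
    k = np.where(k == 0.0, 1e-13, k)
    denom = np.sqrt(1.0 - rho * rho)
    ah = (k / h - rho) / denom
    ak = (h / k - rho) / denom
    beta = np.where(h * k > 0, 0.0, 0.5)
    out = (
        0.5 * (special.ndtr(h) + special.ndtr(k))
        - special.owens_t(h, ah)
        - special.owens_t(k, ak)
        - beta
    )
    return np.clip(out, 0.0, 1.0)


def bvn_cdf(h, k, rho):
    """P(Z1 <= h, Z2 <= k) under a standard bivariate normal with corr rho.

    Vectorised via Owen's T; exact limits at rho = +/-1.
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, float), np.asarray(k, float), np.asarray(rho, float)
    )
    out = np.empty(h.shape, dtype=float)
    hi = rho >= 1.0 - 1e-12
    lo = rho <= -1.0 + 1e-12
    mid = ~(hi | lo)
    if hi.any():
        out[hi] = special.ndtr(np.minimum(h[hi], k[hi]))
    if lo.any():
        out[lo] = np.maximum(special.ndtr(h[lo]) + special.ndtr(k[lo]) - 1.0, 0.0)
    if mid.any():
        out[mid] = _owens_t_bvn(h[mid], k[mid], rho[mid])
    if out.ndim == 0:
        return float(out)
    return out


def dosage_correlation(f1, f2, latent_rho):
    """Expected correlation between two {0,1,2} dosages generated by
    thresholding latent standard normals with correlation ``latent_rho``.

    A haplotype carries the counted allele when its latent z falls below
    Phi^-1(f); the two haplotypes of an individual are independent, so the
    dosage correlation equals the per-haplotype allele correlation.
    """
    t1 = special.ndtri(f1)
    t2 = special.ndtri(f2)
    p11 = bvn_cdf(t1, t2, latent_rho)
    num = p11 - f1 * f2
    den = np.sqrt(f1 * (1.0 - f1) * f2 * (1.0 - f2))
    return num / den


def latent_rho_for_dosage_corr(f1: float, f2: float, target: float) -> float:
    """Invert :func:`dosage_correlation` for the latent correlation giving
    dosage correlation ``target`` (>= 0). Raises InfeasibleLDError when the
    target exceeds what the two allele frequencies allow."""
    if target < 0:
        raise ValueError("target dosage correlation must be non-negative")
    if target == 0:
        return 0.0
    upper = 1.0 - 1e-9
    max_corr = float(dosage_correlation(f1, f2, upper))
    if target > max_corr:
        raise InfeasibleLDError(
            f"dosage correlation {target:.4f} unattainable for MAFs "
            f"({f1:.3f}, {f2:.3f}); maximum is {max_corr:.4f}"
        )
    return float(
        optimize.brentq(
            lambda c: float(dosage_correlation(f1, f2, c)) - target, 0.0, upper, xtol=1e-10
        )
    )
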