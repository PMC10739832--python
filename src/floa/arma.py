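"""ARMA(p, q) correlation structures for within-curve errors.

Kinematic curves are time series, so residuals at neighbouring frames are
serially correlated.  The error covariance is Σ = σ²C where C is the
Toeplitz matrix of the theoretical autocorrelation function of a
stationary, invertible ARMA(p, q) process (unit diagonal: σ² is the
marginal error variance, not the innovation variance).

Unconstrained optimization uses the partial-autocorrelation transform
(Monahan): each of p + q real numbers is mapped into (-1, 1) and then
through the Durbin–Levinson recursion, which enforces stationarity of the
AR polynomial and invertibility of the MA polynomial for every parameter
value.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import toeplitz
from statsmodels.tsa.arima_process import arma_acf, arma_acovf
from statsmodels.tsa.statespace.tools import (
    constrain_stationary_univariate,
    unconstrain_stationary_univariate,
)

__all__ = [
    "arma_correlation",
    "arma_acf_theoretical",
    "is_stationary",
    "is_invertible",
    "constrain_arma",
    "unconstrain_arma",
    "simulate_arma_noise",
]


def is_stationary(coefs: np.ndarray) -> bool:
    """True when the polynomial 1 - c1 z - ... - cp z^p has roots outside
    the unit circle (stationary AR / invertible MA, by symmetry)."""
    c = np.trim_zeros(np.atleast_1d(np.asarray(coefs, dtype=float)), "b")
    if c.size == 0:
        return True
    # roots of 1 - c1 z - ... - cp z^p must all lie outside the unit circle
    roots = np.roots(np.r_[1.0, -c][::-1])
    return bool(np.all(np.abs(roots) > 1.0))


def is_invertible(theta) -> bool:
    """True when 1 + t1 z + ... + tq z^q has all roots outside the unit
    circle (invertible moving-average polynomial)."""
    return is_stationary(-np.atleast_1d(np.asarray(theta, dtype=float)))


def arma_acf_theoretical(phi, theta, lags: int) -> np.ndarray:
    """Theoretical autocorrelation ρ(0..lags-1) of an ARMA(p, q) process."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if phi.size == 0 and theta.size == 0:
        out = np.zeros(lags)
        out[0] = 1.0
        return out
    if not is_stationary(phi):
        raise ValueError(f"non-stationary AR coefficients {phi}")
    if not is_invertible(theta):
        raise ValueError(f"non-invertible MA coefficients {theta}")
    ar = np.r_[1.0, -phi]
    ma = np.r_[1.0, theta]
    return arma_acf(ar, ma, lags=lags)


def arma_correlation(phi, theta, n_frames: int) -> np.ndarray:
    """Toeplitz correlation matrix C of the ARMA ACF, [C]_jk = ρ(|j-k|)."""
    rho = arma_acf_theoretical(phi, theta, n_frames)
    return toeplitz(rho)


def constrain_arma(x: np.ndarray, p: int, q: int):
    """Map p+q unconstrained reals to stationary/invertible (phi, theta)."""
    x = np.asarray(x, dtype=float)
    phi = (constrain_stationary_univariate(x[:p]) if p else np.empty(0))
    theta = (-constrain_stationary_univariate(-x[p:p + q]) if q
             else np.empty(0))
    return phi, theta


def unconstrain_arma(phi, theta) -> np.ndarray:
    """Inverse of :func:`constrain_arma`."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    parts = []
    if phi.size:
        parts.append(unconstrain_stationary_univariate(phi))
    if theta.size:
        parts.append(-unconstrain_stationary_univariate(-theta))
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


def simulate_arma_noise(phi, theta, sigma2: float, shape,
                        rng: np.random.Generator,
                        burn_in: int = 500) -> np.ndarray:
    """Sample ARMA noise paths with marginal variance *sigma2*.

    *shape* is (n_paths, n_frames).  Innovations are scaled so that the
    stationary marginal variance equals sigma2 exactly (the correlation
    matrix has unit diagonal); a burn-in prefix is discarded so the paths
    start in the stationary regime.
    """
    n_paths, n_frames = shape
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if phi.size == 0 and theta.size == 0:
        return rng.normal(0.0, np.sqrt(sigma2), size=(n_paths, n_frames))
    ar = np.r_[1.0, -phi]
    ma = np.r_[1.0, theta]
    gamma0 = arma_acovf(ar, ma, nobs=1, sigma2=1.0)[0]
    innov_sd = np.sqrt(sigma2 / gamma0)
    total = n_frames + burn_in
    eps = rng.normal(0.0, innov_sd, size=(n_paths, total))
    from scipy.signal import lfilter
    paths = lfilter(ma, ar, eps, axis=1)
    return paths[:, burn_in:]
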