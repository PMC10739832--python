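"""Karhunen–Loève eigenbasis for the random-effects design.

The sample covariance S of the observed difference curves is
eigendecomposed, S = Q Λ Q'.  The leading eigenvectors — the smallest set
explaining at least 99% of the variance — form an orthonormal basis for
the random-effect deviation curves.  Because the basis is orthogonal, a
diagonal random-effect covariance is a natural (and much cheaper)
parameterization than the unstructured covariance needed on a B-spline
basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .basis import BasisSystem
from .grid import FrameGrid

__all__ = [
    "SampleCovariance",
    "EigenSelection",
    "sample_covariance",
    "eigendecompose",
    "truncate",
    "EigenBasis",
]

#: eigenvalues below this multiple of the largest are treated as zero
EIGENVALUE_FLOOR = 1e-10


@dataclass(frozen=True)
class SampleCovariance:
    matrix: np.ndarray
    n_curves: int
    centering: str = "sample_mean"

    def __post_init__(self) -> None:
        S = np.asarray(self.matrix)
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("sample covariance not symmetric to 1e-10")


@dataclass(frozen=True)
class EigenSelection:
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_kept: int
    variance_fraction: float


def sample_covariance(curves: np.ndarray,
                      centering: str = "sample_mean") -> SampleCovariance:
    """Unbiased (n-1 denominator) per-frame-pair covariance across curves.

    *curves* is an (n_curves, n_frames) matrix; curves are pooled across
    all subjects/sessions/replicates of a scenario.  With
    ``centering="sample_mean"`` the pointwise mean curve is removed first
    (the expansion assumes a zero-mean process and the true mean curve is
    unknown before the model fit); ``centering="none"`` uses raw curves.
    """
    Y = np.atleast_2d(np.asarray(curves, dtype=float))
    n = Y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 curves for a sample covariance")
    if centering == "sample_mean":
        Y = Y - Y.mean(axis=0, keepdims=True)
    elif centering != "none":
        raise ValueError(f"unknown centering {centering!r}")
    S = Y.T @ Y / (n - 1)
    S = 0.5 * (S + S.T)
    return SampleCovariance(matrix=S, n_curves=n, centering=centering)


def eigendecompose(S: SampleCovariance | np.ndarray) -> EigenSelection:
    """Full eigendecomposition S = QΛQ', eigenvalues sorted descending."""
    M = S.matrix if isinstance(S, SampleCovariance) else np.asarray(S, float)
    if not np.allclose(M, M.T, atol=1e-8 * max(1.0, np.abs(M).max())):
        raise ValueError("matrix is not symmetric")
    w, Q = np.linalg.eigh(0.5 * (M + M.T))
    order = np.argsort(w)[::-1]
    return EigenSelection(eigenvalues=w[order], eigenvectors=Q[:, order],
                          n_kept=len(w), variance_fraction=1.0)


def truncate(E: EigenSelection, variance_fraction: float = 0.99,
             grid: FrameGrid | None = None) -> BasisSystem:
    """Keep the smallest leading eigenvector set reaching *variance_fraction*.

    Eigenvalues below ``EIGENVALUE_FLOOR`` times the largest are treated
    as zero and never kept.  Raises on an all-zero covariance.
    """
    if not 0.0 < variance_fraction <= 1.0:
        raise ValueError("variance_fraction must be in (0, 1]")
    lam = np.maximum(E.eigenvalues, 0.0)
    total = lam.sum()
    if total <= 0.0:
        raise ValueError("all-zero covariance: no eigenbasis to keep")
    nonzero = lam > EIGENVALUE_FLOOR * lam[0]
    cum = np.cumsum(lam) / total
    n_keep = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    n_keep = min(n_keep, int(nonzero.sum()))
    n_keep = max(n_keep, 1)
    sel = EigenSelection(eigenvalues=E.eigenvalues[:n_keep],
                         eigenvectors=E.eigenvectors,
                         n_kept=n_keep, variance_fraction=variance_fraction)
    return BasisSystem(matrix=E.eigenvectors[:, :n_keep], kind="eigen",
                       spec=sel, grid=grid)


class EigenBasis(TransformerMixin, BaseEstimator):
    """Eigenbasis transformer: fit on curves, project onto kept vectors.

    Fitted attributes: ``components_`` (n_kept x n_frames),
    ``eigenvalues_`` (full spectrum, descending), ``n_components_``,
    ``explained_variance_ratio_``, ``basis_`` (the kept vectors as a
    :class:`~floa.basis.BasisSystem`).
    """

    def __init__(self, variance_fraction: float = 0.99,
                 centering: str = "sample_mean",
                 grid: FrameGrid | None = None):
        self.variance_fraction = variance_fraction
        self.centering = centering
        self.grid = grid

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cov = sample_covariance(X, centering=self.centering)
        full = eigendecompose(cov)
        basis = truncate(full, self.variance_fraction, grid=self.grid)
        self.covariance_ = cov
        self.eigenvalues_ = full.eigenvalues
        self.components_ = basis.matrix.T
        self.n_components_ = basis.n_basis
        total = np.maximum(full.eigenvalues, 0.0).sum()
        self.explained_variance_ratio_ = (
            np.maximum(full.eigenvalues, 0.0) / total)
        self.mean_ = (X.mean(axis=0) if self.centering == "sample_mean"
                      else np.zeros(X.shape[1]))
        self.basis_ = basis
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean_) @ self.components_.T

    def scree(self) -> dict:
        """Eigenvalues and cumulative variance fractions (JSON-friendly)."""
        lam = np.maximum(self.eigenvalues_, 0.0)
        cum = np.cumsum(lam) / lam.sum()
        return {"eigenvalues": self.eigenvalues_.tolist(),
                "cumulative_fraction": cum.tolist(),
                "n_kept": int(self.n_components_)}
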