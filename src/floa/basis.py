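"""Cubic B-spline basis systems with equally spaced inner knots.

The mean difference curve and the per-level random deviation curves are
modelled on a regression-spline basis.  Knots are equally spaced on the
normalized-time domain; the boundary knots are clamped (multiplicity
degree+1).  Two dialects are supported for the number of basis functions:

* ``no_intercept`` (default): the first basis function of the clamped
  system is dropped, giving ``n_inner + degree`` columns.  Because curves
  are rebaselined to start at zero (range of motion), the dropped
  function — the only one non-zero at the left endpoint — carries no
  signal.
* ``with_intercept``: the full clamped system, ``n_inner + degree + 1``
  columns, which forms a partition of unity.

The number of inner knots is chosen by an adjusted-R² rule: the smallest
candidate for which a per-curve regression-spline fit reaches adjusted
R² >= 0.95 for every individual curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, TransformerMixin

from .grid import FrameGrid

__all__ = [
    "BSplineSpec",
    "BasisSystem",
    "make_inner_knots",
    "eval_basis",
    "adjusted_r2",
    "select_knots",
    "BSplineBasis",
    "KnotSelector",
]


@dataclass(frozen=True)
class BSplineSpec:
    """Specification of an equally-spaced-knot B-spline system."""

    degree: int = 3
    n_inner_knots: int = 0
    intercept: bool = False

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError(f"degree must be >= 1, got {self.degree}")
        if self.n_inner_knots < 0:
            raise ValueError(
                f"n_inner_knots must be >= 0, got {self.n_inner_knots}"
            )

    @property
    def n_basis(self) -> int:
        n = self.n_inner_knots + self.degree
        return n + 1 if self.intercept else n


@dataclass(frozen=True)
class BasisSystem:
    """An evaluated basis matrix on a frame grid.

    ``matrix`` is n_frames x n_basis; ``kind`` records provenance
    (``"bspline"`` or ``"eigen"``); ``spec`` the generating specification.
    """

    matrix: np.ndarray
    kind: str
    spec: object = None
    grid: FrameGrid = field(default=None)

    @property
    def n_basis(self) -> int:
        return self.matrix.shape[1]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if not np.all(np.isfinite(m)):
            raise ValueError("basis matrix contains non-finite entries")
        if np.any(np.all(m == 0.0, axis=0)):
            raise ValueError("basis matrix contains an all-zero column")


def make_inner_knots(n_inner: int, grid: FrameGrid) -> np.ndarray:
    """Equally spaced interior knots on the open domain of *grid*.

    Boundary knots are excluded; they are supplied by the evaluator with
    multiplicity degree+1 (clamped spline).  One inner knot falls at the
    middle of the domain; three fall at the quartiles, and so on.
    """
    if n_inner < 0:
        raise ValueError(f"n_inner must be >= 0, got {n_inner}")
    edges = np.linspace(grid.t_min, grid.t_max, n_inner + 2)
    return edges[1:-1]


def _full_knot_vector(spec: BSplineSpec, grid: FrameGrid) -> np.ndarray:
    inner = make_inner_knots(spec.n_inner_knots, grid)
    d = spec.degree
    return np.concatenate(
        [np.full(d + 1, grid.t_min), inner, np.full(d + 1, grid.t_max)]
    )


def eval_basis(grid: FrameGrid, spec: BSplineSpec) -> BasisSystem:
    """Evaluate the B-spline system of *spec* on *grid*.

    Returns a matrix with ``spec.n_basis`` columns.  Raises if the knot
    spacing collapses below the grid resolution (degenerate basis).
    """
    knots = _full_knot_vector(spec, grid)
    grid_step = (grid.t_max - grid.t_min) / (grid.n_frames - 1)
    inner = knots[spec.degree + 1 : -(spec.degree + 1)]
    if inner.size and np.min(np.diff(np.concatenate(
            [[grid.t_min], inner, [grid.t_max]]))) < grid_step:
        raise ValueError(
            f"{spec.n_inner_knots} inner knots are degenerate on a "
            f"{grid.n_frames}-frame grid (knot spacing below grid step)"
        )
    design = BSpline.design_matrix(grid.points, knots, spec.degree).toarray()
    if not spec.intercept:
        design = design[:, 1:]
    return BasisSystem(matrix=design, kind="bspline", spec=spec, grid=grid)


def adjusted_r2(curve: np.ndarray, basis: BasisSystem | np.ndarray) -> float:
    """Adjusted R² of a least-squares fit of *curve* on the basis columns.

    Computed as ``1 - (RSS/(n-q)) / (TSS/(n-1))`` with q the number of
    fitted coefficients and TSS the centered total sum of squares.  A
    constant curve has TSS = 0 and raises, as the statistic is undefined.
    """
    y = np.asarray(curve, dtype=float)
    X = basis.matrix if isinstance(basis, BasisSystem) else np.asarray(basis)
    n = y.shape[0]
    if X.shape[0] != n:
        raise ValueError("curve length does not match basis rows")
    q = X.shape[1]
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("adjusted R² undefined for a constant curve")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ coef) ** 2))
    return 1.0 - (rss / (n - q)) / (tss / (n - 1))


def select_knots(
    curves: np.ndarray | Sequence[np.ndarray],
    candidates: Sequence[int] = (0, 1, 3, 9, 19, 32),
    threshold: float = 0.95,
    grid: FrameGrid | None = None,
    degree: int = 3,
    intercept: bool = False,
) -> BSplineSpec:
    """Pick the smallest inner-knot count whose basis fits every curve.

    For each candidate, a separate regression spline is fitted to each
    individual curve; the candidate qualifies when the minimum adjusted R²
    over curves reaches *threshold*.  If no candidate qualifies the largest
    is returned and flagged (attribute ``attained`` on the selector is the
    class-based interface for that flag).
    """
    sel = KnotSelector(
        candidates=tuple(candidates), threshold=threshold, degree=degree,
        intercept=intercept, grid=grid,
    )
    sel.fit(np.atleast_2d(np.asarray(curves, dtype=float)))
    return sel.spec_


class BSplineBasis(TransformerMixin, BaseEstimator):
    """B-spline basis transformer: curves in, spline coefficients out.

    ``fit`` infers the frame grid from the curve length (or accepts one);
    ``transform`` returns per-curve least-squares coefficients on the
    basis; the evaluated design matrix is ``design_matrix_``.
    """

    def __init__(self, degree: int = 3, n_inner_knots: int = 9,
                 intercept: bool = False, grid: FrameGrid | None = None):
        self.degree = degree
        self.n_inner_knots = n_inner_knots
        self.intercept = intercept
        self.grid = grid

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        grid = self.grid or FrameGrid(n_frames=X.shape[1], t_min=0.0,
                                      t_max=float(X.shape[1] - 1))
        spec = BSplineSpec(self.degree, self.n_inner_knots, self.intercept)
        self.grid_ = grid
        self.basis_ = eval_basis(grid, spec)
        self.design_matrix_ = self.basis_.matrix
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        coef, _, _, _ = np.linalg.lstsq(self.design_matrix_, X.T, rcond=None)
        return coef.T

    def inverse_transform(self, coefs):
        return np.asarray(coefs) @ self.design_matrix_.T


class KnotSelector(BaseEstimator):
    """Adjusted-R² knot selection over a candidate list.

    Fitted attributes: ``n_inner_knots_`` (selected count), ``spec_``,
    ``attained_`` (False when no candidate met the threshold and the
    largest was returned), ``report_`` (per-candidate min/median adjusted
    R² over curves).
    """

    def __init__(self, candidates=(0, 1, 3, 9, 19, 32), threshold: float = 0.95,
                 degree: int = 3, intercept: bool = False,
                 grid: FrameGrid | None = None):
        self.candidates = candidates
        self.threshold = threshold
        self.degree = degree
        self.intercept = intercept
        self.grid = grid

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 0:
            raise ValueError("empty curve set")
        cands = list(self.candidates)
        if not cands or sorted(cands) != cands:
            raise ValueError("candidates must be non-empty and ascending")
        grid = self.grid or FrameGrid(n_frames=X.shape[1], t_min=0.0,
                                      t_max=float(X.shape[1] - 1))
        report = {}
        chosen = None
        for k in cands:
            basis = eval_basis(grid, BSplineSpec(self.degree, k, self.intercept))
            r2 = np.array([adjusted_r2(c, basis) for c in X])
            report[k] = {"min": float(r2.min()), "median": float(np.median(r2))}
            if chosen is None and r2.min() >= self.threshold:
                chosen = k
        self.attained_ = chosen is not None
        self.n_inner_knots_ = chosen if chosen is not None else cands[-1]
        self.spec_ = BSplineSpec(self.degree, self.n_inner_knots_, self.intercept)
        self.report_ = report
        self.grid_ = grid
        return self
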