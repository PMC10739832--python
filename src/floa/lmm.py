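"""REML estimation of the three-level functional mixed model.

The between-method difference curves d_ijk (subject i, session j,
replicate k) are modelled as

    d_ijk = X b + Z1 u_i + Z2 u_ij + Z3 u_ijk + e_ijk,

with u_i ~ N(0, Psi1), u_ij ~ N(0, Psi2), u_ijk ~ N(0, Psi3) and
e_ijk ~ N(0, sigma2 * C) where C is an ARMA(p, q) correlation matrix over
frames.  X holds the fixed-effect B-spline basis; the Z matrices hold the
random-effect basis (the same B-spline system with an unstructured
covariance, or a covariance eigenbasis with a diagonal covariance).

Estimation is restricted maximum likelihood with the fixed effects
profiled out by GLS.  Variance parameters are optimized on an
unconstrained scale: log-Cholesky factors for unstructured covariances,
log variances for diagonal ones, log sigma2, and a
partial-autocorrelation transform for the ARMA coefficients.

Subject blocks are independent, so the restricted likelihood decomposes
by subject.  For balanced designs (every subject with the same complete
session x replicate layout) the per-subject covariance has a nested
exchangeable structure over curves, which an orthogonal contrast
transform (Helmert over replicates and over sessions) block-diagonalizes
into three distinct n_frames x n_frames blocks — this is what makes the
fit fast.  Unbalanced data use dense per-subject blocks; the two paths
agree to numerical tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .arma import arma_correlation, constrain_arma, unconstrain_arma
from .basis import BasisSystem
from .datasets import DifferenceCurves

__all__ = [
    "RandomLevelSpec",
    "ErrorSpec",
    "VarianceParams",
    "FLoAModel",
    "build_designs",
    "marginal_covariance",
    "reml_criterion",
    "fit_reml",
    "blup",
    "count_variance_parameters",
]

_NEG_INF = -np.inf
_LEVELS = ("subject", "session", "replicate")


@dataclass
class RandomLevelSpec:
    """Random-effect specification for one grouping level."""

    level: str
    basis: BasisSystem
    covariance: str = "unstructured"

    def __post_init__(self) -> None:
        if self.level not in _LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.covariance not in ("unstructured", "diagonal"):
            raise ValueError(f"unknown covariance {self.covariance!r}")

    @property
    def q(self) -> int:
        return self.basis.n_basis

    @property
    def n_params(self) -> int:
        q = self.q
        return q * (q + 1) // 2 if self.covariance == "unstructured" else q


@dataclass
class ErrorSpec:
    """Within-curve error: family and ARMA orders.

    ``car1`` is the continuous-time AR(1); on an equally spaced grid it is
    an AR(1) with positive autoregressive coefficient.
    """

    family: str = "arma"
    p: int = 2
    q: int = 1

    def __post_init__(self) -> None:
        fam = self.family.lower()
        if fam not in ("iid", "ar1", "car1", "arma"):
            raise ValueError(f"unknown error family {self.family!r}")
        self.family = fam
        if fam == "iid":
            self.p, self.q = 0, 0
        elif fam in ("ar1", "car1"):
            self.p, self.q = 1, 0

    @property
    def n_params(self) -> int:
        return self.p + self.q

    def label(self) -> str:
        if self.family == "iid":
            return "iid"
        if self.family == "car1":
            return "CAR1"
        if self.family == "ar1":
            return "AR1"
        return f"ARMA({self.p},{self.q})"


@dataclass
class VarianceParams:
    """Variance components: per-level covariances, error variance, ARMA."""

    psi: dict[str, np.ndarray]
    sigma2: float
    phi: np.ndarray = field(default_factory=lambda: np.empty(0))
    theta: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class FLoAModel:
    """A fitted functional mixed model."""

    beta: np.ndarray
    params: VarianceParams
    fixed_basis: BasisSystem
    levels: list[RandomLevelSpec]
    error_spec: ErrorSpec
    blups: dict = field(default_factory=dict)
    reml_loglik: float = np.nan
    converged: bool = False
    fit_meta: dict = field(default_factory=dict)

    def summary_dict(self) -> dict:
        """JSON-serializable model summary."""
        return {
            "beta": self.beta.tolist(),
            "sigma2": float(self.params.sigma2),
            "phi": np.asarray(self.params.phi).tolist(),
            "theta": np.asarray(self.params.theta).tolist(),
            "psi_diag": {lv: np.diag(m).tolist()
                         for lv, m in self.params.psi.items()},
            "error": self.error_spec.label(),
            "reml_loglik": float(self.reml_loglik),
            "converged": bool(self.converged),
            "fit_meta": {k: v for k, v in self.fit_meta.items()
                         if np.isscalar(v) or isinstance(v, (str, bool))},
        }


# ---------------------------------------------------------------------------
# design construction


@dataclass
class DesignBundle:
    """Stacked responses and design bookkeeping, grouped by subject."""

    X: np.ndarray                       # n_frames x p fixed design
    levels: list[RandomLevelSpec]
    subjects: list
    curve_keys: dict                    # subject -> ordered [(session, rep)]
    y: dict                             # subject -> stacked response
    n_frames: int
    balanced: bool
    m_sessions: int = 0
    n_replicates: int = 0
    flags: list = field(default_factory=list)
    # balanced-path precomputations (contrast-transformed responses)
    ty_mean: np.ndarray | None = None   # (n_subj, n_frames) grand-mean dir
    ty_sess: np.ndarray | None = None   # (n_subj*(m-1), n_frames)
    ty_rep: np.ndarray | None = None    # (n_subj*m*(r-1), n_frames)

    @property
    def n_obs(self) -> int:
        return sum(v.size for v in self.y.values())

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def level(self, name: str) -> RandomLevelSpec | None:
        for spec in self.levels:
            if spec.level == name:
                return spec
        return None


def _helmert(n: int) -> np.ndarray:
    """Orthonormal n x n matrix whose first column is 1/sqrt(n)."""
    u = np.full((n, 1), 1.0 / np.sqrt(n))
    H = np.linalg.qr(np.hstack([u, np.eye(n)[:, : n - 1]]))[0]
    # QR may flip signs; force first column positive
    if H[0, 0] < 0:
        H = -H
    return H


def build_designs(diffs: DifferenceCurves, fixed_basis: BasisSystem,
                  levels: list[RandomLevelSpec]) -> DesignBundle:
    """Organize difference curves into per-subject stacked blocks.

    Verifies grid compatibility, detects balance (for the fast REML path)
    and flags unidentifiable configurations (e.g. a session level with a
    single session per subject).
    """
    nf = diffs.grid.n_frames
    if fixed_basis.matrix.shape[0] != nf:
        raise ValueError("fixed basis grid does not match data grid")
    for spec in levels:
        if spec.basis.matrix.shape[0] != nf:
            raise ValueError(f"{spec.level} basis grid does not match data")
    subjects = diffs.subjects
    curve_keys, y = {}, {}
    for s in subjects:
        keys = sorted(k[1:] for k in diffs.diffs if k[0] == s)
        curve_keys[s] = keys
        y[s] = np.concatenate([diffs.diffs[(s, *k)] for k in keys])

    sess_counts = {s: sorted({k[0] for k in curve_keys[s]}) for s in subjects}
    rep_layout_ok = True
    m = len(sess_counts[subjects[0]])
    reps0 = None
    for s in subjects:
        sess = sess_counts[s]
        if len(sess) != m:
            rep_layout_ok = False
            break
        for j in sess:
            reps = sorted(k[1] for k in curve_keys[s] if k[0] == j)
            if reps0 is None:
                reps0 = reps
            if reps != reps0:
                rep_layout_ok = False
                break
    r = len(reps0) if reps0 else 0
    balanced = rep_layout_ok and m >= 1 and r >= 1

    flags = []
    if len(subjects) < 2 and any(l.level == "subject" for l in levels):
        flags.append("subject level unidentifiable: fewer than 2 subjects")
    if balanced and m < 2 and any(l.level == "session" for l in levels):
        flags.append("session level unidentifiable: single session")
    if balanced and r < 2 and any(l.level == "replicate" for l in levels):
        flags.append("replicate level weakly identified: single replicate")
    for f in flags:
        warnings.warn(f, stacklevel=2)

    bundle = DesignBundle(X=fixed_basis.matrix, levels=list(levels),
                          subjects=subjects, curve_keys=curve_keys, y=y,
                          n_frames=nf, balanced=balanced,
                          m_sessions=m if balanced else 0,
                          n_replicates=r if balanced else 0, flags=flags)
    if balanced:
        Um, Ur = _helmert(m), _helmert(r)
        ty_mean, ty_sess, ty_rep = [], [], []
        for s in subjects:
            cube = y[s].reshape(m, r, nf)
            t = np.einsum("ja,kb,jkf->abf", Um, Ur, cube)
            ty_mean.append(t[0, 0])
            if m > 1:
                ty_sess.append(t[1:, 0])
            if r > 1:
                ty_rep.append(t[:, 1:].reshape(m * (r - 1), nf))
        bundle.ty_mean = np.array(ty_mean)
        bundle.ty_sess = (np.concatenate(ty_sess) if ty_sess
                          else np.empty((0, nf)))
        bundle.ty_rep = (np.concatenate(ty_rep) if ty_rep
                         else np.empty((0, nf)))
    return bundle


# ---------------------------------------------------------------------------
# parameter packing (unconstrained <-> natural)


class ParamMap:
    """Bijection between VarianceParams and an unconstrained real vector.

    Unstructured covariances use a log-Cholesky factor (log on the
    diagonal), diagonal covariances use log variances, sigma2 a log, and
    the ARMA coefficients the partial-autocorrelation transform.  The
    ``car1`` family constrains the single AR coefficient to (0, 1).
    """

    def __init__(self, levels: list[RandomLevelSpec], error_spec: ErrorSpec):
        self.levels = levels
        self.error_spec = error_spec
        self.n_params = (sum(l.n_params for l in levels) + 1
                         + error_spec.n_params)

    def pack(self, params: VarianceParams) -> np.ndarray:
        x = []
        for spec in self.levels:
            psi = np.asarray(params.psi[spec.level], dtype=float)
            if spec.covariance == "diagonal":
                x.append(0.5 * np.log(np.maximum(np.diag(psi), 1e-12)))
            else:
                L = np.linalg.cholesky(psi + 1e-10 * np.trace(psi)
                                       / psi.shape[0] * np.eye(psi.shape[0]))
                tril = L[np.tril_indices_from(L)]
                idx = np.cumsum(np.arange(1, psi.shape[0] + 1)) - 1
                tril[idx] = np.log(np.maximum(L[np.diag_indices_from(L)],
                                              1e-12))
                x.append(tril)
        x.append([0.5 * np.log(max(params.sigma2, 1e-12))])
        es = self.error_spec
        if es.family == "car1":
            phi = float(np.atleast_1d(params.phi)[0]) if np.size(params.phi) \
                else 0.5
            phi = min(max(phi, 1e-6), 1 - 1e-6)
            x.append([np.log(phi / (1 - phi))])
        elif es.n_params:
            x.append(unconstrain_arma(params.phi, params.theta))
        return np.concatenate([np.atleast_1d(np.asarray(v, float))
                               for v in x])

    def unpack(self, x: np.ndarray) -> VarianceParams:
        x = np.asarray(x, dtype=float)
        pos = 0
        psi = {}
        for spec in self.levels:
            q = spec.q
            if spec.covariance == "diagonal":
                v = np.exp(2.0 * x[pos: pos + q])
                psi[spec.level] = np.diag(v)
                pos += q
            else:
                k = q * (q + 1) // 2
                tril = x[pos: pos + k].copy()
                pos += k
                L = np.zeros((q, q))
                L[np.tril_indices(q)] = tril
                d = np.exp(np.diag(L).copy())
                L[np.diag_indices(q)] = d
                psi[spec.level] = L @ L.T
        sigma2 = float(np.exp(2.0 * x[pos]))
        pos += 1
        es = self.error_spec
        if es.family == "car1":
            phi = np.array([1.0 / (1.0 + np.exp(-x[pos]))])
            theta = np.empty(0)
        elif es.n_params:
            phi, theta = constrain_arma(x[pos: pos + es.n_params], es.p, es.q)
        else:
            phi, theta = np.empty(0), np.empty(0)
        return VarianceParams(psi=psi, sigma2=sigma2, phi=phi, theta=theta)


# ---------------------------------------------------------------------------
# covariance assembly and the REML criterion


def _component_blocks(params: VarianceParams, designs: DesignBundle):
    """Per-curve covariance pieces: curve-local W, session-coupling P2,
    subject-coupling P1 (each n_frames x n_frames)."""
    nf = designs.n_frames
    C = arma_correlation(params.phi, params.theta, nf)
    W = params.sigma2 * C
    spec3 = designs.level("replicate")
    if spec3 is not None:
        Z3 = spec3.basis.matrix
        W = W + Z3 @ params.psi["replicate"] @ Z3.T
    P2 = np.zeros((nf, nf))
    spec2 = designs.level("session")
    if spec2 is not None:
        Z2 = spec2.basis.matrix
        P2 = Z2 @ params.psi["session"] @ Z2.T
    P1 = np.zeros((nf, nf))
    spec1 = designs.level("subject")
    if spec1 is not None:
        Z1 = spec1.basis.matrix
        P1 = Z1 @ params.psi["subject"] @ Z1.T
    return W, P2, P1


def marginal_covariance(params: VarianceParams, designs: DesignBundle,
                        subject) -> np.ndarray:
    """Dense covariance of one subject's stacked response vector.

    The subject-level term couples all the subject's curves, the
    session-level term couples curves within a session, and the
    replicate-level term plus the error covariance are curve-local.
    """
    W, P2, P1 = _component_blocks(params, designs)
    keys = designs.curve_keys[subject]
    nc, nf = len(keys), designs.n_frames
    V = np.zeros((nc * nf, nc * nf))
    for a in range(nc):
        for b in range(nc):
            block = P1.copy()
            if keys[a][0] == keys[b][0]:
                block = block + P2
            if a == b:
                block = block + W
            V[a * nf:(a + 1) * nf, b * nf:(b + 1) * nf] = block
    return V


def _chol_logdet(V):
    c, low = cho_factor(V, lower=True, check_finite=False)
    return (c, low), 2.0 * np.sum(np.log(np.diag(c)))


def reml_criterion(params: VarianceParams, designs: DesignBundle) -> float:
    """Restricted log-likelihood with beta profiled out by GLS.

    Returns -inf when the marginal covariance is numerically singular.
    Balanced designs are evaluated through the contrast transform; the
    result is identical (to numerical tolerance) to the dense per-subject
    computation.
    """
    out = _reml_core(params, designs)
    return out[0] if out is not None else _NEG_INF


def _reml_core(params: VarianceParams, designs: DesignBundle):
    """Returns (loglik, beta, u=X'V^-1 y, A=X'V^-1 X) or None if singular."""
    X = designs.X
    N, p = designs.n_obs, designs.p
    try:
        W, P2, P1 = _component_blocks(params, designs)
    except ValueError:
        return None
    try:
        if designs.balanced:
            m, r = designs.m_sessions, designs.n_replicates
            V1 = W + r * P2 + m * r * P1
            (c1, logdet1) = _chol_logdet(V1)
            logdet = logdet1 * len(designs.subjects)
            yty = 0.0
            s1 = cho_solve(c1, designs.ty_mean.T, check_finite=False)
            yty += float(np.sum(designs.ty_mean.T * s1))
            XtViX = m * r * len(designs.subjects) * (
                X.T @ cho_solve(c1, X, check_finite=False))
            u = np.sqrt(m * r) * (X.T @ s1).sum(axis=1)
            if designs.ty_sess.size:
                V2 = W + r * P2
                (c2, logdet2) = _chol_logdet(V2)
                logdet += logdet2 * designs.ty_sess.shape[0]
                s2 = cho_solve(c2, designs.ty_sess.T, check_finite=False)
                yty += float(np.sum(designs.ty_sess.T * s2))
            if designs.ty_rep.size:
                (c3, logdet3) = _chol_logdet(W)
                logdet += logdet3 * designs.ty_rep.shape[0]
                s3 = cho_solve(c3, designs.ty_rep.T, check_finite=False)
                yty += float(np.sum(designs.ty_rep.T * s3))
        else:
            logdet = 0.0
            yty = 0.0
            XtViX = np.zeros((p, p))
            u = np.zeros(p)
            for s in designs.subjects:
                V = marginal_covariance(params, designs, s)
                (c, ld) = _chol_logdet(V)
                logdet += ld
                ys = designs.y[s]
                Xs = np.tile(X, (len(designs.curve_keys[s]), 1))
                sv = cho_solve(c, np.column_stack([ys, Xs]),
                               check_finite=False)
                yty += float(ys @ sv[:, 0])
                u += Xs.T @ sv[:, 0]
                XtViX += Xs.T @ sv[:, 1:]
    except np.linalg.LinAlgError:
        return None
    sign, logdetA = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return None
    try:
        beta = np.linalg.solve(XtViX, u)
    except np.linalg.LinAlgError:
        return None
    quad = yty - float(beta @ u)
    loglik = -0.5 * (logdet + logdetA + quad + (N - p) * np.log(2.0 * np.pi))
    if not np.isfinite(loglik):
        return None
    return loglik, beta, u, XtViX


# ---------------------------------------------------------------------------
# analytic REML gradient (balanced path)
#
# d(-2 l_R)/dθ = tr(V⁻¹V̇) − tr(A⁻¹ X'V⁻¹V̇V⁻¹X) − r'V⁻¹V̇V⁻¹r
# with A = X'V⁻¹X and r the marginal GLS residual (envelope theorem: β̂
# need not be differentiated).  Every V̇ is either Z D Z' for a per-level
# covariance parameter or σ²·(dC) for the error parameters, so all traces
# reduce to small q×q (or p×q) contractions after one set of solves.


def _grad_from_G(G: np.ndarray, spec: RandomLevelSpec,
                 psi: np.ndarray) -> np.ndarray:
    """Map the symmetric matrix G = dcriterion/dPsi onto the unconstrained
    per-level parameters (log-Cholesky or log-variance chain rule)."""
    if spec.covariance == "diagonal":
        return 2.0 * np.diag(psi) * np.diag(G)
    L = np.linalg.cholesky(psi + 1e-300 * np.eye(psi.shape[0]))
    GL = G @ L
    q = psi.shape[0]
    out = np.empty(q * (q + 1) // 2)
    idx = 0
    for i in range(q):
        for j in range(i + 1):
            if i == j:
                out[idx] = 2.0 * L[i, i] * GL[i, i]
            else:
                out[idx] = 2.0 * GL[i, j]
            idx += 1
    return out


def _arma_c_dot(pmap: "ParamMap", x_arma: np.ndarray, nf: int,
                h: float = 1e-6):
    """Finite-difference derivatives of the correlation matrix C with
    respect to each unconstrained ARMA coordinate."""
    es = pmap.error_spec

    def corr(xa):
        if es.family == "car1":
            phi = np.array([1.0 / (1.0 + np.exp(-xa[0]))])
            theta = np.empty(0)
        else:
            phi, theta = constrain_arma(xa, es.p, es.q)
        return arma_correlation(phi, theta, nf)

    C0 = corr(x_arma)
    dots = []
    for j in range(x_arma.size):
        xp = x_arma.copy()
        xp[j] += h
        dots.append((corr(xp) - C0) / h)
    return C0, dots


def reml_value_and_grad(x: np.ndarray, pmap: "ParamMap",
                        designs: DesignBundle):
    """Negative restricted log-likelihood and its analytic gradient on the
    unconstrained scale (balanced designs only)."""
    if not designs.balanced:
        raise ValueError("analytic gradient requires a balanced design")
    params = pmap.unpack(x)
    X = designs.X
    N, p = designs.n_obs, designs.p
    n_s = len(designs.subjects)
    m, r = designs.m_sessions, designs.n_replicates
    nf = designs.n_frames
    try:
        W, P2, P1 = _component_blocks(params, designs)
    except ValueError:
        return 1e12, np.zeros(pmap.n_params)

    # block kinds: 0 grand-mean, 1 session contrasts, 2 replicate contrasts
    blocks = [(0, W + r * P2 + m * r * P1, designs.ty_mean)]
    if designs.ty_sess.size:
        blocks.append((1, W + r * P2, designs.ty_sess))
    if designs.ty_rep.size:
        blocks.append((2, W, designs.ty_rep))

    try:
        chols = [cho_factor(V, lower=True, check_finite=False)
                 for _, V, _ in blocks]
    except np.linalg.LinAlgError:
        return 1e12, np.zeros(pmap.n_params)

    logdet = sum(T.shape[0] * 2.0 * np.sum(np.log(np.diag(c[0])))
                 for c, (_, V, T) in zip(chols, blocks))
    S = [cho_solve(c, T.T, check_finite=False)      # nf x n_vec
         for c, (_, V, T) in zip(chols, blocks)]
    Vinv = [cho_solve(c, np.eye(nf), check_finite=False) for c in chols]
    R1 = cho_solve(chols[0], X, check_finite=False)  # V1^-1 X
    A = n_s * m * r * (X.T @ R1)
    u = np.sqrt(m * r) * X.T @ S[0].sum(axis=1)
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return 1e12, np.zeros(pmap.n_params)
    Ainv = np.linalg.inv(A)
    beta = Ainv @ u
    yty = sum(float(np.sum(T.T * s)) for (_, V, T), s in zip(blocks, S))
    quad = yty - float(beta @ u)
    neg2 = logdet + logdetA + quad + (N - p) * np.log(2.0 * np.pi)
    value = 0.5 * neg2  # = -l_R

    # residual solves: Shat_b = V_b^-1 (T_b - fixed part)'
    Shat = list(S)
    Shat[0] = S[0] - np.sqrt(m * r) * (R1 @ beta)[:, None]

    # per-level coefficients of V̇ in each block: V1, V2, V3
    coef = {"subject": (m * r, 0.0, 0.0), "session": (r, r, 0.0),
            "replicate": (1.0, 1.0, 1.0)}
    grad = np.empty(pmap.n_params)
    pos = 0
    for spec in pmap.levels:
        Z = spec.basis.matrix
        c_l = coef[spec.level]
        G = np.zeros((spec.q, spec.q))
        for (kind, V, T), vi, sh in zip(blocks, Vinv, Shat):
            cb = c_l[kind]
            if cb == 0.0:
                continue
            ZtVi = Z.T @ vi
            G += cb * T.shape[0] * (ZtVi @ Z)
            Zs = Z.T @ sh
            G -= cb * (Zs @ Zs.T)
        # A-correction (block 1 only)
        if c_l[0]:
            H = Z.T @ R1                      # q x p
            G -= c_l[0] * n_s * m * r * (H @ Ainv @ H.T)
        g = _grad_from_G(G, spec, params.psi[spec.level])
        grad[pos: pos + spec.n_params] = 0.5 * g
        pos += spec.n_params

    # sigma2 and ARMA parameters: V̇ = d(sigma2 * C)
    es = pmap.error_spec
    x_arma = x[pos + 1: pos + 1 + es.n_params]
    C0, C_dots = _arma_c_dot(pmap, x_arma, nf)
    mats = [2.0 * params.sigma2 * C0] + \
           [params.sigma2 * cd for cd in C_dots]
    XtV1 = R1.T                                # p x nf (V1^-1 X)'
    for j, M in enumerate(mats):
        g = 0.0
        for (_, V, T), vi, sh in zip(blocks, Vinv, Shat):
            g += T.shape[0] * float(np.sum(vi * M))
            g -= float(np.sum(sh * (M @ sh)))
        g -= n_s * m * r * float(np.trace(Ainv @ (XtV1 @ M @ R1)))
        grad[pos + j] = 0.5 * g
    if not np.all(np.isfinite(grad)):
        return 1e12, np.zeros(pmap.n_params)
    return value, grad


# ---------------------------------------------------------------------------
# fitting


def count_variance_parameters(levels: list[RandomLevelSpec],
                              error_spec: ErrorSpec) -> int:
    """Total variance-parameter count: per-level covariance parameters
    (q(q+1)/2 unstructured, q diagonal) + 1 (sigma2) + ARMA p + q."""
    return sum(l.n_params for l in levels) + 1 + error_spec.n_params


def psi_parameter_subtotal(levels: list[RandomLevelSpec]) -> int:
    """Covariance-only parameter count, excluding sigma2 and ARMA terms."""
    return sum(l.n_params for l in levels)


def _yule_walker_init(resid: np.ndarray, p: int) -> np.ndarray:
    """AR(p) start values from the pooled residual autocorrelation."""
    nf, nc = resid.shape
    r = resid - resid.mean(axis=0, keepdims=True)
    denom = float(np.sum(r * r))
    rho = np.array([1.0] + [
        float(np.sum(r[:-h] * r[h:])) / denom for h in range(1, p + 1)])
    from scipy.linalg import toeplitz as _toep
    try:
        phi = np.linalg.solve(_toep(rho[:p]), rho[1: p + 1])
    except np.linalg.LinAlgError:
        return np.zeros(p)
    from .arma import is_stationary
    scale = 1.0
    while not is_stationary(phi * scale) and scale > 1e-3:
        scale *= 0.9
    return phi * scale


def _moment_start(diffs: DifferenceCurves, designs: DesignBundle,
                  error_spec: ErrorSpec | None = None) -> VarianceParams:
    """Moment-based initial values from per-curve spline fits."""
    X = designs.X
    Y = diffs.to_matrix()
    keys = diffs.index
    coef_x, _, _, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ coef_x
    # sigma2 start: residual variance after projecting out the fixed basis
    # AND every random-effect basis (those directions belong to the random
    # effects, not the error)
    XZ = np.hstack([X] + [spec.basis.matrix for spec in designs.levels])
    Q = np.linalg.qr(XZ)[0]
    rz = Y.T - Q @ (Q.T @ Y.T)
    dof = max(X.shape[0] - Q.shape[1], 1)
    sigma2 = float(np.mean(np.sum(rz ** 2, axis=0) / dof))
    sigma2 = max(sigma2, 1e-8)
    # ARMA start from the fully projected residuals: residuals on the fixed
    # basis alone still contain the smooth random-effect deviations, whose
    # near-integrated autocorrelation would start the optimizer inside the
    # boundary-spike basin
    phi0 = np.empty(0)
    if error_spec is not None and error_spec.p > 0 \
            and X.shape[0] > error_spec.p + 2:
        if error_spec.family == "car1":
            phi0 = np.clip(_yule_walker_init(rz, 1), 0.05, 0.99)
        else:
            phi0 = _yule_walker_init(rz, error_spec.p)
    mean_curve = Y.mean(axis=0)
    dev = Y - mean_curve
    psi = {}
    for spec in designs.levels:
        Z = spec.basis.matrix
        c, _, _, _ = np.linalg.lstsq(Z, dev.T, rcond=None)
        c = c.T  # n_curves x q
        df = pd.DataFrame(c)
        labels = pd.DataFrame(keys, columns=["subject", "session",
                                             "replicate"])
        subj_mean = df.groupby(labels["subject"]).transform("mean")
        sess_mean = df.groupby(
            [labels["subject"], labels["session"]]).transform("mean")
        if spec.level == "subject":
            per_subj = df.groupby(labels["subject"]).mean()
            v = per_subj.var(ddof=1).to_numpy() if len(per_subj) > 1 \
                else np.full(spec.q, 0.1)
        elif spec.level == "session":
            v = (sess_mean - subj_mean).var(ddof=1).to_numpy()
        else:
            v = (df - sess_mean).var(ddof=1).to_numpy()
        v = np.nan_to_num(np.asarray(v, float), nan=0.1)
        v = np.maximum(v, 1e-4 * max(sigma2, 1e-4))
        psi[spec.level] = np.diag(v)
    theta0 = (np.zeros(error_spec.q) if error_spec is not None
              else np.empty(0))
    return VarianceParams(psi=psi, sigma2=sigma2, phi=phi0, theta=theta0)


def fit_reml(diffs: DifferenceCurves, fixed_basis: BasisSystem,
             levels: list[RandomLevelSpec], error_spec: ErrorSpec,
             n_starts: int = 3, seed: int = 0, maxiter: int = 2000,
             ftol: float = 1e-11, gtol: float = 1e-6) -> FLoAModel:
    """Maximize the restricted likelihood and return the fitted model.

    Start 1 uses moment-based initial values (pooled residual variance
    from per-curve spline fits; per-level between-group coefficient
    variances); further starts jitter the unconstrained vector.  On
    non-convergence the best point found is returned with
    ``converged=False``.
    """
    designs = build_designs(diffs, fixed_basis, levels)
    pmap = ParamMap(levels, error_spec)
    start = _moment_start(diffs, designs, error_spec)
    x0 = pmap.pack(start)
    if x0.size != pmap.n_params:
        x0 = np.concatenate([x0, np.zeros(pmap.n_params - x0.size)])

    # box bounds keep log-scale parameters off -inf (boundary variance
    # components) and the ARMA coordinates in a numerically safe range
    bounds = []
    for spec in levels:
        if spec.covariance == "diagonal":
            bounds += [(-8.0, 8.0)] * spec.q
        else:
            for i in range(spec.q):
                for j in range(i + 1):
                    bounds.append((-8.0, 8.0) if i == j else (-60.0, 60.0))
    bounds.append((-8.0, 8.0))          # log sigma
    # partial autocorrelations are kept inside ±0.95: likelihood spikes at
    # the stationarity boundary (a nearly integrated error process
    # impersonating the smooth signal) are a known ARMA pathology
    arma_cap = 0.95 / np.sqrt(1.0 - 0.95 ** 2)
    bounds += [(-arma_cap, arma_cap)] * error_spec.n_params

    rng = np.random.default_rng(seed)

    if designs.balanced:
        def neg(x):
            return reml_value_and_grad(x, pmap, designs)
        jac = True
    else:
        def neg(x):
            val = reml_criterion(pmap.unpack(x), designs)
            if not np.isfinite(val):
                return 1e12
            return -val
        jac = None

    best = None
    n_iter_total = 0
    for s in range(max(n_starts, 1)):
        xs = x0 if s == 0 else x0 + rng.normal(0.0, 0.3, size=x0.size)
        res = minimize(neg, xs, method="L-BFGS-B", jac=jac, bounds=bounds,
                       options={"maxiter": maxiter, "ftol": ftol,
                                "gtol": gtol, "maxcor": 25})
        n_iter_total += res.nit
        if best is None or res.fun < best.fun:
            best = res

    params = pmap.unpack(best.x)
    core = _reml_core(params, designs)
    if core is None:
        raise RuntimeError("REML criterion not finite at the optimum")
    loglik, beta, _, XtViX = core
    model = FLoAModel(beta=beta, params=params, fixed_basis=fixed_basis,
                      levels=list(levels), error_spec=error_spec,
                      reml_loglik=loglik,
                      converged=bool(best.success),
                      fit_meta={"n_iter": int(n_iter_total),
                                "n_starts": int(max(n_starts, 1)),
                                "message": str(best.message),
                                "n_obs": designs.n_obs,
                                "n_variance_params": pmap.n_params,
                                "balanced": designs.balanced})
    model.blups = blup(model, designs)
    model.fit_meta["designs"] = designs
    return model


def blup(model: FLoAModel, designs: DesignBundle) -> dict:
    """Best linear unbiased prediction of all random-effect coefficients.

    Standard conditional mean: for each group g at a level with covariance
    Psi and design Z, b_g = Psi Z' V^{-1} (y - X beta) restricted to the
    rows of the group.  Returned as {level: {group_key: coefficient
    vector}}.
    """
    X = designs.X
    nf = designs.n_frames
    out = {spec.level: {} for spec in designs.levels}
    for s in designs.subjects:
        keys = designs.curve_keys[s]
        nc = len(keys)
        V = marginal_covariance(model.params, designs, s)
        Xs = np.tile(X, (nc, 1))
        resid = designs.y[s] - Xs @ model.beta
        K = np.linalg.solve(V, resid)  # V^{-1} r, length nc*nf
        Kc = K.reshape(nc, nf)
        for spec in designs.levels:
            Z = spec.basis.matrix
            psi = model.params.psi[spec.level]
            if spec.level == "subject":
                out["subject"][s] = psi @ (Z.T @ Kc.sum(axis=0))
            elif spec.level == "session":
                for j in sorted({k[0] for k in keys}):
                    rows = [a for a, k in enumerate(keys) if k[0] == j]
                    out["session"][(s, j)] = psi @ (Z.T @ Kc[rows].sum(axis=0))
            else:
                for a, k in enumerate(keys):
                    out["replicate"][(s, *k)] = psi @ (Z.T @ Kc[a])
    return out
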