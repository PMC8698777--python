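"""Regularized reconstruction: single-step linear, Gauss-Newton, total
variation, difference-of-absolute-images, and the regularized
method-of-moments inversion.

The functional cores (`linear_gtr`, `gauss_newton`, `tv_pdipm`, ...) are
plain functions; thin scikit-learn-style estimators wrap them so the
solvers compose with pipelines and parameter search (`fit` binds the
system matrix / forward problem, `transform` maps measurement frames to
images; fitted attributes carry a trailing underscore).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, TransformerMixin

from .forward import FEMForwardProblem
from .mesh import PixelGrid, TriMesh
from .mom import MoMatrix, sigma_from_coeffs

__all__ = [
    "SolverReport",
    "prior_matrix",
    "edge_matrix",
    "linear_gtr",
    "gauss_newton",
    "tv_pdipm",
    "difference_of_absolute",
    "mom_regularized",
    "LinearGTRReconstructor",
    "GaussNewtonReconstructor",
    "TVReconstructor",
    "DifferenceOfAbsoluteReconstructor",
    "MoMRegularizedReconstructor",
]


@dataclass
class SolverReport:
    """Outcome of one iterative reconstruction."""

    image: np.ndarray
    objective_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "objective_trace": [float(v) for v in self.objective_trace],
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "diagnostics": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                            for k, v in self.diagnostics.items()},
        }


# --------------------------------------------------------------------------
# priors and adjacency
# --------------------------------------------------------------------------

def _adjacency_pairs(domain: TriMesh | PixelGrid) -> np.ndarray:
    """Interior adjacencies as (n_pairs, 2) index pairs."""
    if isinstance(domain, TriMesh):
        tri = domain.triangles
        e = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        key = np.sort(e, axis=1)
        elem = np.tile(np.arange(len(tri)), 3)
        order = np.lexsort((key[:, 1], key[:, 0]))
        key, elem = key[order], elem[order]
        same = np.all(key[1:] == key[:-1], axis=1)
        return np.column_stack([elem[:-1][same], elem[1:][same]])
    if isinstance(domain, PixelGrid):
        rc = {(int(r), int(c)): i
              for i, (r, c) in enumerate(zip(domain.rows, domain.cols))}
        pairs = []
        for (r, c), i in rc.items():
            for dr, dc in ((0, 1), (1, 0)):
                j = rc.get((r + dr, c + dc))
                if j is not None:
                    pairs.append((i, j))
        return np.array(pairs, dtype=int).reshape(-1, 2)
    raise TypeError("domain must be a TriMesh or PixelGrid")


def prior_matrix(kind: str, domain: TriMesh | PixelGrid | None = None,
                 J: np.ndarray | None = None, L: int | None = None) -> np.ndarray:
    """Regularization matrix Q: 'tikhonov' (identity), 'laplace' (graph
    Laplacian of the element/pixel adjacency) or 'noser'
    (diag(J^T J)^(1/2))."""
    if kind in ("tikhonov", "identity"):
        if L is None:
            if domain is None:
                raise ValueError("identity prior needs L or a domain")
            L = domain.n_elements if isinstance(domain, TriMesh) else domain.L
        return np.eye(L)
    if kind == "laplace":
        if domain is None:
            raise ValueError("laplace prior needs the mesh or grid")
        n = domain.n_elements if isinstance(domain, TriMesh) else domain.L
        pairs = _adjacency_pairs(domain)
        Q = np.zeros((n, n))
        for i, j in pairs:
            Q[i, i] += 1.0
            Q[j, j] += 1.0
            Q[i, j] -= 1.0
            Q[j, i] -= 1.0
        return Q
    if kind == "noser":
        if J is None:
            raise ValueError("noser prior needs the Jacobian")
        return np.diag(np.sqrt(np.sum(np.asarray(J) ** 2, axis=0)))
    raise ValueError(f"unknown prior kind {kind!r}")


def edge_matrix(domain: TriMesh | PixelGrid) -> sp.csr_matrix:
    """Signed incidence over interior adjacencies: one row per shared edge,
    entries +1 and -1."""
    pairs = _adjacency_pairs(domain)
    n = domain.n_elements if isinstance(domain, TriMesh) else domain.L
    ned = len(pairs)
    rows = np.repeat(np.arange(ned), 2)
    cols = pairs.ravel()
    vals = np.tile([1.0, -1.0], ned)
    return sp.csr_matrix((vals, (rows, cols)), shape=(ned, n))


# --------------------------------------------------------------------------
# single-step linear (closed-form generalized Tikhonov)
# --------------------------------------------------------------------------

def linear_gtr(A: np.ndarray, dv: np.ndarray, Q: np.ndarray,
               lam: float) -> np.ndarray:
    """Closed-form generalized-Tikhonov solution
    x* = (A^T A + lam^2 Q)^{-1} A^T dv (uniform channel weighting)."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    A = np.asarray(A, float)
    H = A.T @ A + lam * lam * np.asarray(Q, float)
    try:
        c = cho_factor(H)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular regularized normal matrix") from exc
    return cho_solve(c, A.T @ np.asarray(dv, float))


# --------------------------------------------------------------------------
# non-linear Gauss-Newton (time-difference and absolute variants)
# --------------------------------------------------------------------------

def gauss_newton(problem: FEMForwardProblem, dv: np.ndarray, Q: np.ndarray,
                 lam: float, sigma0: np.ndarray | float = 1.0,
                 max_iter: int = 8, tol: float = 1e-4,
                 damping_halvings: int = 8) -> SolverReport:
    """Damped Gauss-Newton for the time-difference objective
    F(ds) = ||U(sigma0 + ds) - U(sigma0) - dv||^2 + lam^2 ds^T Q ds.

    Starts from the closed-form linear solution; the Jacobian is recomputed
    at every iterate; steps are halved until the objective decreases.
    """
    sigma0 = np.broadcast_to(np.asarray(sigma0, float), (problem.n_elements,)).copy()
    U0 = problem.solve(sigma0)
    floor = 1e-6 * float(np.min(sigma0))

    def objective(ds):
        r = problem.solve(np.maximum(sigma0 + ds, floor)) - U0 - dv
        return float(r @ r + lam * lam * ds @ Q @ ds)

    J = problem.jacobian(sigma0)
    ds = linear_gtr(J, dv, Q, lam)
    trace = [objective(ds)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sigma = np.maximum(sigma0 + ds, floor)
        J = problem.jacobian(sigma)
        r = problem.solve(sigma) - U0 - dv
        if not np.all(np.isfinite(r)):
            return SolverReport(ds, trace, it, False,
                                {"error": "non-finite forward residual"})
        g = J.T @ r + lam * lam * (Q @ ds)
        H = J.T @ J + lam * lam * Q
        step = np.linalg.solve(H, -g)
        s, accepted = 1.0, False
        for _ in range(damping_halvings + 1):
            f_new = objective(ds + s * step)
            if f_new < trace[-1]:
                ds = ds + s * step
                trace.append(f_new)
                accepted = True
                break
            s *= 0.5
        if not accepted:
            converged = True
            break
        if abs(trace[-2] - trace[-1]) <= tol * max(trace[-2], 1e-300):
            converged = True
            break
    return SolverReport(ds, trace, it, converged)


def absolute_gauss_newton(problem: FEMForwardProblem, v: np.ndarray,
                          Q: np.ndarray, lam: float, max_iter: int = 8,
                          tol: float = 1e-4,
                          damping_halvings: int = 8) -> SolverReport:
    """Absolute-imaging Gauss-Newton:
    F(sigma) = ||U(sigma) - v||^2 + lam^2 sigma^T Q sigma.

    Initialized at the best-fit homogeneous conductivity (1-parameter line
    search; U scales as 1/sigma for a homogeneous medium so the search is
    over log-conductivity).
    """
    n = problem.n_elements
    U1 = problem.solve(np.ones(n))

    def mis(logt):
        u = U1 / np.exp(logt)
        r = u - v
        return float(r @ r)

    res = minimize_scalar(mis, bracket=(-2.0, 0.0, 2.0))
    sig_h = float(np.exp(res.x))
    sigma = np.full(n, sig_h)
    floor = 1e-6 * sig_h

    def objective(s):
        r = problem.solve(np.maximum(s, floor)) - v
        return float(r @ r + lam * lam * s @ Q @ s)

    trace = [objective(sigma)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        J = problem.jacobian(sigma)
        r = problem.solve(sigma) - v
        g = J.T @ r + lam * lam * (Q @ sigma)
        H = J.T @ J + lam * lam * Q
        step = np.linalg.solve(H, -g)
        s, accepted = 1.0, False
        for _ in range(damping_halvings + 1):
            cand = np.maximum(sigma + s * step, floor)
            f_new = objective(cand)
            if f_new < trace[-1]:
                sigma = cand
                trace.append(f_new)
                accepted = True
                break
            s *= 0.5
        if not accepted:
            converged = True
            break
        if abs(trace[-2] - trace[-1]) <= tol * max(trace[-2], 1e-300):
            converged = True
            break
    return SolverReport(sigma, trace, it, converged,
                        {"homogeneous_init": sig_h})


def difference_of_absolute(v1: np.ndarray, v2: np.ndarray,
                           problem: FEMForwardProblem, Q: np.ndarray,
                           lam: float = 5e-2, **gn_kwargs) -> SolverReport:
    """Two absolute reconstructions, subtracted: ds* = sigma*(2) - sigma*(1)."""
    r1 = absolute_gauss_newton(problem, np.asarray(v1, float), Q, lam, **gn_kwargs)
    r2 = absolute_gauss_newton(problem, np.asarray(v2, float), Q, lam, **gn_kwargs)
    return SolverReport(r2.image - r1.image,
                        [r1.objective_trace[-1], r2.objective_trace[-1]],
                        r1.n_iter + r2.n_iter,
                        r1.converged and r2.converged,
                        {"sigma1": r1.image, "sigma2": r2.image})


# --------------------------------------------------------------------------
# total variation, primal-dual interior point
# --------------------------------------------------------------------------

def tv_pdipm(J: np.ndarray, dv: np.ndarray, edge: sp.spmatrix, lam: float,
             beta: float = 1e-3, max_iter: int = 50,
             tol: float = 1e-8) -> SolverReport:
    """PD-IPM minimization of
    F(x) = ||J x - dv||^2 + lam^2 sum_i sqrt((L x)_i^2 + beta).

    The dual variable is kept feasible (|y| <= 1) by the smoothed-gradient
    scaling y = Lx / sqrt((Lx)^2 + beta); the primal Newton system uses the
    standard anisotropic weighting and steps are backtracked on the true
    objective. lam = 0 degenerates to the least-squares solution.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    J = np.asarray(J, float)
    dv = np.asarray(dv, float)
    Ld = edge.toarray() if sp.issparse(edge) else np.asarray(edge, float)
    alpha = lam * lam
    JtJ = J.T @ J

    def objective(x):
        r = J @ x - dv
        return float(r @ r + alpha * np.sum(np.sqrt((Ld @ x) ** 2 + beta)))

    # start from the least-squares / lightly regularized solution
    x = np.linalg.lstsq(J, dv, rcond=None)[0] if alpha == 0 else \
        linear_gtr(J, dv, Ld.T @ Ld + 1e-12 * np.eye(J.shape[1]), lam if lam > 0 else 1e-6)
    y = np.zeros(Ld.shape[0])
    trace = [objective(x)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lx = Ld @ x
        eta = np.sqrt(lx * lx + beta)
        Fdiag = np.clip(1.0 - y * lx / eta, 1e-6, None)
        H = 2.0 * JtJ + alpha * (Ld.T * (Fdiag / eta)) @ Ld
        g = 2.0 * J.T @ (J @ x - dv) + alpha * (Ld.T @ y)
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            return SolverReport(x, trace, it, False, {"error": "singular Newton system"})
        s, accepted = 1.0, False
        for _ in range(12):
            f_new = objective(x + s * step)
            if f_new < trace[-1]:
                x = x + s * step
                trace.append(f_new)
                accepted = True
                break
            s *= 0.5
        if not accepted:
            break
        lx = Ld @ x
        y = lx / np.sqrt(lx * lx + beta)          # dual-feasible by construction
        if abs(trace[-2] - trace[-1]) <= tol * max(abs(trace[-2]), 1e-300):
            converged = True
            break
    else:
        converged = True
    return SolverReport(x, trace, it, converged or len(trace) > 1,
                        {"stalled": not converged})


# --------------------------------------------------------------------------
# regularized method-of-moments
# --------------------------------------------------------------------------

def mom_regularized(Mo: MoMatrix, dv: np.ndarray, Q: np.ndarray,
                    lam: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form RBF-weight solution for the MoM system, mapped to a
    conductivity-change image. Returns (delta_sigma_image, coefficients)."""
    c = linear_gtr(Mo.M, dv, Q, lam)
    sigma = sigma_from_coeffs(c, Mo.grid, Mo.params, Mo.sigma0)
    return sigma - Mo.sigma0, c


# --------------------------------------------------------------------------
# estimator wrappers
# --------------------------------------------------------------------------

def _resolve_prior(prior, domain, J, L):
    if isinstance(prior, str):
        return prior_matrix(prior, domain=domain, J=J, L=L)
    return np.asarray(prior, float)


class LinearGTRReconstructor(TransformerMixin, BaseEstimator):
    """Single-step generalized-Tikhonov reconstruction on any system matrix.

    Parameters
    ----------
    prior : 'tikhonov' | 'laplace' | 'noser' or an (L, L) array
    lam : regularization hyperparameter (default from the thorax study:
        8e-3 for the FEM Jacobian).
    """

    def __init__(self, prior: str = "laplace", lam: float = 8e-3):
        self.prior = prior
        self.lam = lam

    def fit(self, A: np.ndarray, y=None, *, domain=None):
        A = np.asarray(A, float)
        Q = _resolve_prior(self.prior, domain, A, A.shape[1])
        self.A_ = A
        self.factor_ = cho_factor(A.T @ A + self.lam ** 2 * Q)
        self.n_channels_ = A.shape[0]
        self.n_pixels_ = A.shape[1]
        return self

    def transform(self, dV: np.ndarray) -> np.ndarray:
        dV = np.atleast_2d(np.asarray(dV, float))
        return cho_solve(self.factor_, self.A_.T @ dV.T).T


class GaussNewtonReconstructor(TransformerMixin, BaseEstimator):
    """Iterative non-linear Gauss-Newton difference imaging."""

    def __init__(self, prior: str = "laplace", lam: float = 8e-3,
                 max_iter: int = 8, tol: float = 1e-4):
        self.prior = prior
        self.lam = lam
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, problem: FEMForwardProblem, y=None, *, sigma0=1.0):
        self.problem_ = problem
        self.sigma0_ = sigma0
        self.Q_ = _resolve_prior(self.prior, problem.mesh, None, problem.n_elements)
        return self

    def transform(self, dV: np.ndarray) -> np.ndarray:
        dV = np.atleast_2d(np.asarray(dV, float))
        self.reports_ = [gauss_newton(self.problem_, v, self.Q_, self.lam,
                                      sigma0=self.sigma0_,
                                      max_iter=self.max_iter, tol=self.tol)
                         for v in dV]
        return np.array([r.image for r in self.reports_])


class TVReconstructor(TransformerMixin, BaseEstimator):
    """Total-variation (PD-IPM) difference imaging on a linear system."""

    def __init__(self, lam: float = 1e-6, beta: float = 1e-3,
                 max_iter: int = 50):
        self.lam = lam
        self.beta = beta
        self.max_iter = max_iter

    def fit(self, A: np.ndarray, y=None, *, domain=None, edge=None):
        self.A_ = np.asarray(A, float)
        self.edge_ = edge if edge is not None else edge_matrix(domain)
        return self

    def transform(self, dV: np.ndarray) -> np.ndarray:
        dV = np.atleast_2d(np.asarray(dV, float))
        self.reports_ = [tv_pdipm(self.A_, v, self.edge_, self.lam,
                                  self.beta, self.max_iter) for v in dV]
        return np.array([r.image for r in self.reports_])


class DifferenceOfAbsoluteReconstructor(TransformerMixin, BaseEstimator):
    """Absolute GN per frame, differenced against the first frame.

    ``transform`` takes *absolute* frames (n_frames, n_channels); row 0 is
    the reference; the output has n_frames - 1 difference images.
    """

    def __init__(self, prior: str = "laplace", lam: float = 5e-2,
                 max_iter: int = 6, tol: float = 1e-4):
        self.prior = prior
        self.lam = lam
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, problem: FEMForwardProblem, y=None):
        self.problem_ = problem
        self.Q_ = _resolve_prior(self.prior, problem.mesh, None, problem.n_elements)
        return self

    def transform(self, V: np.ndarray) -> np.ndarray:
        V = np.atleast_2d(np.asarray(V, float))
        ref = absolute_gauss_newton(self.problem_, V[0], self.Q_, self.lam,
                                    max_iter=self.max_iter, tol=self.tol)
        self.reports_ = [ref]
        out = []
        for v in V[1:]:
            r = absolute_gauss_newton(self.problem_, v, self.Q_, self.lam,
                                      max_iter=self.max_iter, tol=self.tol)
            self.reports_.append(r)
            out.append(r.image - ref.image)
        return np.array(out)


class MoMRegularizedReconstructor(TransformerMixin, BaseEstimator):
    """Closed-form regularized PM-MoM (default Laplace prior, lam = 0.2)."""

    def __init__(self, prior: str = "laplace", lam: float = 0.2):
        self.prior = prior
        self.lam = lam

    def fit(self, Mo: MoMatrix, y=None):
        self.Mo_ = Mo
        Q = _resolve_prior(self.prior, Mo.grid, Mo.M, Mo.grid.L)
        self.factor_ = cho_factor(Mo.M.T @ Mo.M + self.lam ** 2 * Q)
        return self

    def transform(self, dV: np.ndarray) -> np.ndarray:
        dV = np.atleast_2d(np.asarray(dV, float))
        C = cho_solve(self.factor_, self.Mo_.M.T @ dV.T).T
        self.coefficients_ = C
        return np.array([sigma_from_coeffs(c, self.Mo_.grid, self.Mo_.params,
                                           self.Mo_.sigma0) - self.Mo_.sigma0
                         for c in C])
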