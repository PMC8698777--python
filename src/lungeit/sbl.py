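"""Overlapping-cluster sparse Bayesian learning for the MoM system.

The RBF weight vector c in Mo c = dV is modelled as the superposition of
g = L - h + 1 sliding clusters of h consecutive coefficients (row-major
pixel order), c = Psi x, with x zero-mean Gaussian whose covariance is
block-diagonal: per-cluster scale gamma_i times an intra-cluster Toeplitz
correlation B_i. An EM loop estimates the posterior mean/covariance of x
(E-step) together with the noise variance gamma_o, the cluster scales
(majoration-minimization update) and the Toeplitz correlations (averaged
first-off-diagonal ratio, magnitude capped at 0.99). The MAP weight
estimate is c* = Psi mu_x, converted to conductivity through the RBF
expansion of the log-conductivity.

The posterior mean is mu_x = Sigma0 Phi^T Sigma_u^{-1} dV, the standard
block-SBL E-step consistent with the residual term of the noise update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, toeplitz
from sklearn.base import BaseEstimator, TransformerMixin

from .mom import MoMatrix, sigma_from_coeffs
from .solvers import SolverReport

__all__ = [
    "ClusterStructure",
    "SBLState",
    "build_clusters",
    "expand_coeffs",
    "expansion_matrix",
    "sbl_initialize",
    "sbl_iterate",
    "sbl_solve",
    "SBLReconstructor",
]

_GAMMA_FLOOR = 1e-12


@dataclass
class ClusterStructure:
    """g = L - h + 1 overlapping windows of h consecutive coefficients."""

    L: int
    h: int

    def __post_init__(self) -> None:
        if not 1 <= self.h <= self.L:
            raise ValueError("need 1 <= h <= L")

    @property
    def g(self) -> int:
        return self.L - self.h + 1

    def pixels(self, i: int) -> range:
        """Pixels covered by cluster i (0-based)."""
        return range(i, i + self.h)


def build_clusters(L: int, h: int) -> ClusterStructure:
    return ClusterStructure(int(L), int(h))


def expand_coeffs(x: np.ndarray, clusters: ClusterStructure) -> np.ndarray:
    """c = Psi x without forming Psi: c_j = sum over clusters covering j."""
    g, h = clusters.g, clusters.h
    x = np.asarray(x, float)
    if x.shape != (g * h,):
        raise ValueError(f"x must have length g*h = {g * h}")
    xr = x.reshape(g, h)
    c = np.zeros(clusters.L)
    for k in range(h):
        c[k:k + g] += xr[:, k]
    return c


def expansion_matrix(clusters: ClusterStructure) -> np.ndarray:
    """Dense Psi (L x gh); intended for small problems and cross-checks."""
    g, h = clusters.g, clusters.h
    Psi = np.zeros((clusters.L, g * h))
    for i in range(g):
        for k in range(h):
            Psi[i + k, i * h + k] = 1.0
    return Psi


@dataclass
class SBLState:
    """All quantities carried across EM iterations.

    Per-cluster posterior covariance is kept as the (g, h, h) diagonal
    blocks (the only part the updates need); the full gh x gh covariance is
    available through :func:`posterior_covariance` for small problems.
    """

    clusters: ClusterStructure
    mu: np.ndarray                 # (gh,)
    Sigma_blocks: np.ndarray       # (g, h, h)
    gamma_o: float
    gamma: np.ndarray              # (g,)
    B: np.ndarray                  # (g, h, h) Toeplitz correlations
    B_acc: np.ndarray              # (g, h, h) accumulators B-tilde
    zeta: float
    eps: float = 1.0
    kappa: int = 0
    Phi3: np.ndarray | None = None   # (Nm, g, h), cached Mo Psi
    Sigma_u: np.ndarray | None = None
    eps_trace: list = field(default_factory=list)
    gamma_o_trace: list = field(default_factory=list)

    def coefficients(self) -> np.ndarray:
        return expand_coeffs(self.mu, self.clusters)


def _phi3(Mo: np.ndarray, clusters: ClusterStructure) -> np.ndarray:
    """Phi = Mo Psi laid out as (Nm, g, h): Phi3[:, i, k] = Mo[:, i + k]."""
    win = np.lib.stride_tricks.sliding_window_view(Mo, clusters.h, axis=1)
    return np.ascontiguousarray(win)


def _sigma_u(gamma_o: float, gamma: np.ndarray, B: np.ndarray,
             Phi3: np.ndarray) -> np.ndarray:
    Nm = Phi3.shape[0]
    gb = gamma[:, None, None] * B
    return gamma_o * np.eye(Nm) + np.einsum("ngh,ghk,mgk->nm", Phi3, gb, Phi3)


def _chol(Sigma_u: np.ndarray):
    try:
        return cho_factor(Sigma_u, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(Sigma_u) / Sigma_u.shape[0]
        return cho_factor(Sigma_u + jitter * np.eye(Sigma_u.shape[0]), lower=True)


def sbl_initialize(Mo: np.ndarray | MoMatrix, dv: np.ndarray, h: int = 4,
                   zeta: float = 0.9) -> SBLState:
    """Initial EM state: zero posterior, unit cluster scales, noise variance
    at 1% of the sample variance of the data, Toeplitz(1, zeta, ...,
    zeta^(h-1)) intra-cluster correlation."""
    M = Mo.M if isinstance(Mo, MoMatrix) else np.asarray(Mo, float)
    dv = np.asarray(dv, float)
    if M.shape[0] != dv.shape[0]:
        raise ValueError("Mo and dv are inconsistent")
    clusters = build_clusters(M.shape[1], h)
    g = clusters.g
    gamma_o = 0.01 * float(np.var(dv, ddof=1)) if dv.size > 1 else 0.0
    gamma_o = max(gamma_o, _GAMMA_FLOOR)
    B0 = toeplitz(zeta ** np.arange(h))
    B = np.broadcast_to(B0, (g, h, h)).copy()
    Phi3 = _phi3(M, clusters)
    gamma = np.ones(g)
    state = SBLState(clusters=clusters,
                     mu=np.zeros(g * h),
                     Sigma_blocks=np.zeros((g, h, h)),
                     gamma_o=gamma_o, gamma=gamma,
                     B=B, B_acc=B.copy(), zeta=zeta,
                     Phi3=Phi3)
    state.Sigma_u = _sigma_u(gamma_o, gamma, B, Phi3)
    return state


def sbl_iterate(state: SBLState, dv: np.ndarray) -> SBLState:
    """One EM pass (posterior, noise, scales, correlations, refresh)."""
    dv = np.asarray(dv, float)
    Phi3 = state.Phi3
    g, h = state.clusters.g, state.clusters.h
    gB = state.gamma[:, None, None] * state.B          # Sigma0 blocks

    c = _chol(state.Sigma_u)
    z = cho_solve(c, dv)                               # Sigma_u^{-1} dv
    Nm = dv.shape[0]
    W = cho_solve(c, Phi3.reshape(Nm, g * h)).reshape(Nm, g, h)

    b = np.einsum("ngh,n->gh", Phi3, z)                # Phi_i^T z
    mu_new = np.einsum("ghk,gk->gh", gB, b)            # Sigma0 Phi^T Sigma_u^{-1} dv
    T = np.einsum("ngh,ngk->ghk", Phi3, W)             # Phi_i^T Sigma_u^{-1} Phi_i
    Sigma_blocks = gB - np.einsum("ghk,gkl,glm->ghm", gB, T, gB)

    # noise variance (residual + posterior-uncertainty correction)
    resid = dv - np.einsum("ngh,gh->n", Phi3, mu_new)
    G2 = np.einsum("ngh,ngk->ghk", Phi3, Phi3)         # Phi_i^T Phi_i
    gamma_o = (resid @ resid + float(np.einsum("ghk,gkh->", Sigma_blocks, G2))) / Nm
    gamma_o = max(gamma_o, _GAMMA_FLOOR)

    # MM update of the cluster scales
    Bb = np.einsum("ghk,gk->gh", state.B, b)
    num = np.linalg.norm(Bb, axis=1)
    den = np.sqrt(np.maximum(np.einsum("ghk,gkh->g", T, state.B), _GAMMA_FLOOR))
    gamma = np.maximum(state.gamma * num / den, _GAMMA_FLOOR)

    # accumulate second moments and re-fit the Toeplitz correlations
    outer = np.einsum("gh,gk->ghk", mu_new, mu_new)
    B_acc = state.B_acc + (Sigma_blocks + outer) / gamma[:, None, None]
    if h > 1:
        diag = np.einsum("ghh->gh", B_acc).mean(axis=1)
        off = np.diagonal(B_acc, offset=1, axis1=1, axis2=2).mean(axis=1)
        r_t = off / np.where(diag == 0, _GAMMA_FLOOR, diag)
        r = np.sign(r_t) * np.minimum(np.abs(r_t), 0.99)
        # B_i = Toeplitz(r^0, ..., r^(h-1)), signed powers
        k = np.abs(np.subtract.outer(np.arange(h), np.arange(h)))
        B = np.where(r[:, None, None] < 0, (-1.0) ** k[None], 1.0) \
            * np.abs(r)[:, None, None] ** k[None]
        B[:, np.arange(h), np.arange(h)] = 1.0
    else:
        B = np.ones((g, 1, 1))
        r = np.zeros(g)

    mu_flat = mu_new.reshape(-1)
    dmu = np.linalg.norm(mu_flat - state.mu)
    nrm = np.linalg.norm(mu_flat)
    eps = dmu / nrm if nrm > 0 else 0.0

    if not (np.all(np.isfinite(mu_flat)) and np.isfinite(gamma_o)
            and np.all(np.isfinite(gamma))):
        raise FloatingPointError("non-finite SBL update")

    new = SBLState(clusters=state.clusters, mu=mu_flat,
                   Sigma_blocks=Sigma_blocks, gamma_o=gamma_o, gamma=gamma,
                   B=B, B_acc=B_acc, zeta=state.zeta, eps=eps,
                   kappa=state.kappa + 1, Phi3=Phi3,
                   eps_trace=state.eps_trace + [eps],
                   gamma_o_trace=state.gamma_o_trace + [gamma_o])
    new.Sigma_u = _sigma_u(gamma_o, gamma, B, Phi3)
    return new


def posterior_covariance(state: SBLState) -> np.ndarray:
    """Full gh x gh posterior covariance Sigma_x = Sigma0 - Sigma0 Phi^T
    Sigma_u^{-1} Phi Sigma0 at the state's current hyperparameters.
    Intended for small problems (dense)."""
    g, h = state.clusters.g, state.clusters.h
    Nm = state.Phi3.shape[0]
    Phi = state.Phi3.reshape(Nm, g * h)
    gB = state.gamma[:, None, None] * state.B
    Sigma0 = np.zeros((g * h, g * h))
    for i in range(g):
        Sigma0[i * h:(i + 1) * h, i * h:(i + 1) * h] = gB[i]
    c = _chol(state.Sigma_u)
    W = cho_solve(c, Phi)
    return Sigma0 - Sigma0 @ Phi.T @ W @ Sigma0


def posterior_mean(state: SBLState, dv: np.ndarray) -> np.ndarray:
    """mu_x = Sigma0 Phi^T Sigma_u^{-1} dv at the current hyperparameters."""
    c = _chol(state.Sigma_u)
    z = cho_solve(c, np.asarray(dv, float))
    gB = state.gamma[:, None, None] * state.B
    b = np.einsum("ngh,n->gh", state.Phi3, z)
    return np.einsum("ghk,gk->gh", gB, b).reshape(-1)


def sbl_solve(Mo: MoMatrix | np.ndarray, dv: np.ndarray, h: int = 4,
              eps_min: float = 1e-5, kappa_max: int = 5, zeta: float = 0.9,
              sigma0: float | None = None, grid=None, params=None
              ) -> tuple[np.ndarray, SolverReport]:
    """Full SBL reconstruction.

    Iterates the EM pass until the relative posterior-mean change drops
    below ``eps_min`` or ``kappa_max`` iterations have been exceeded
    (so at most kappa_max + 1 passes run). Returns the conductivity-change
    image (sigma - sigma0 when grid context is available, otherwise the
    expanded coefficient vector) and a solver report.
    """
    state = sbl_initialize(Mo, np.asarray(dv, float), h=h, zeta=zeta)
    while state.eps > eps_min and state.kappa <= kappa_max:
        state = sbl_iterate(state, np.asarray(dv, float))
    c = state.coefficients()
    if isinstance(Mo, MoMatrix):
        grid = grid or Mo.grid
        params = params or Mo.params
        sigma0 = Mo.sigma0 if sigma0 is None else sigma0
    if grid is not None:
        image = sigma_from_coeffs(c, grid, params, sigma0 or 1.0) - (sigma0 or 1.0)
    else:
        image = c
    report = SolverReport(image, state.eps_trace, state.kappa,
                          state.eps <= eps_min or state.kappa > kappa_max,
                          {"eps_trace": list(state.eps_trace),
                           "gamma_o_trace": list(state.gamma_o_trace),
                           "cluster_energy": np.linalg.norm(
                               state.mu.reshape(state.clusters.g, state.clusters.h),
                               axis=1).tolist()})
    return image, report


class SBLReconstructor(TransformerMixin, BaseEstimator):
    """Sparse-Bayesian-learning PM-MoM reconstruction (sklearn-style)."""

    def __init__(self, h: int = 4, eps_min: float = 1e-5, kappa_max: int = 5,
                 zeta: float = 0.9):
        self.h = h
        self.eps_min = eps_min
        self.kappa_max = kappa_max
        self.zeta = zeta

    def fit(self, Mo: MoMatrix, y=None):
        self.Mo_ = Mo
        return self

    def transform(self, dV: np.ndarray) -> np.ndarray:
        dV = np.atleast_2d(np.asarray(dV, float))
        out, self.reports_ = [], []
        for v in dV:
            img, rep = sbl_solve(self.Mo_, v, h=self.h, eps_min=self.eps_min,
                                 kappa_max=self.kappa_max, zeta=self.zeta)
            out.append(img)
            self.reports_.append(rep)
        return np.array(out)
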