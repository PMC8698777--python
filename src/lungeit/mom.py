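"""Point-matching method-of-moments system matrix.

Instead of linearizing the forward map around a background conductivity,
the governing elliptic equation is recast as a global integral equation:

    u(r) = u0(r) + int_Omega G(r, r') grad ln sigma(r') . grad u0(r') dA',

where G is the Neumann Green's function of the Laplacian on the domain and
u0 the homogeneous-background potential of the driven electrode pair. The
log-conductivity is expanded over generalized-exponential radial basis
functions centred at the pixel centers, ln sigma = ln sigma0 + sum_j c_j
theta_j, and collocating the boundary observations at the (point)
electrodes yields a linear system Mo c = dU whose unknowns are the RBF
weights. Because the conductivity enters through its logarithm, Mo captures
more of the nonlinearity than the FEM Jacobian does.

The Green's function is analytic on the unit disk and computed by an
auxiliary FEM solve on arbitrary (thorax-shaped) domains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from .forward import _stiffness
from .mesh import PixelGrid, StimPattern, TriMesh

__all__ = [
    "RBFParams",
    "GreensTable",
    "MoMatrix",
    "disk_green",
    "disk_green_gradient",
    "numeric_green",
    "greens_table_disk",
    "rbf_value",
    "rbf_gradient",
    "homogeneous_u0",
    "assemble_Mo",
    "sigma_from_coeffs",
]


@dataclass
class RBFParams:
    """Generalized-exponential RBF theta(d) = exp(-||d||_p1^(p1/p2) / (2 D^2)).

    p1 = 2, p2 = 1 is the Gaussian; D sets the kernel width (same length
    units as the grid).
    """

    p1: int = 2
    p2: int = 1
    D: float = 1.0

    def __post_init__(self) -> None:
        if self.p1 <= 0 or self.p1 % 2:
            raise ValueError("p1 must be a positive even integer")
        if self.p2 <= 0:
            raise ValueError("p2 must be a positive integer")
        if self.D <= 0:
            raise ValueError("D must be positive")


def rbf_value(r: np.ndarray, rJ: np.ndarray, params: RBFParams) -> np.ndarray:
    """theta(r, rJ); broadcasts over leading axes of r and rJ."""
    d = np.asarray(r, float) - np.asarray(rJ, float)
    p1, p2, D = params.p1, params.p2, params.D
    s = np.sum(np.abs(d) ** p1, axis=-1) ** (1.0 / p1)   # p1-norm
    return np.exp(-(s ** (p1 / p2)) / (2.0 * D * D))


def rbf_gradient(r: np.ndarray, rJ: np.ndarray, params: RBFParams) -> np.ndarray:
    """Analytic gradient of theta with respect to r (same broadcasting)."""
    d = np.asarray(r, float) - np.asarray(rJ, float)
    p1, p2, D = params.p1, params.p2, params.D
    m = p1 / p2
    sp1 = np.sum(np.abs(d) ** p1, axis=-1)               # ||d||_p1 ^ p1
    with np.errstate(divide="ignore", invalid="ignore"):
        # d theta/d r_k = theta * (-m/(2D^2)) * s^(m-p1) * d_k^(p1-1)
        s_pow = np.where(sp1 > 0, sp1 ** (m / p1 - 1.0), 0.0)
    theta = np.exp(-(sp1 ** (m / p1)) / (2.0 * D * D))
    coef = theta * (-m / (2.0 * D * D)) * s_pow
    return coef[..., None] * (d ** (p1 - 1))


# --------------------------------------------------------------------------
# Green's functions
# --------------------------------------------------------------------------

def disk_green(r: np.ndarray, r_src: np.ndarray) -> np.ndarray:
    """Neumann Green's function of the Laplacian on the unit disk.

    Satisfies -Lap G = delta - 1/pi (uniform compensating sink), insulating
    boundary, mean-zero gauge, and G(a, b) = G(b, a). The closed form is
    the free-space logarithm plus its Kelvin image and a quadratic sink
    term::

        G = -(1/2pi) [ ln|r - r'| + (1/2) ln(|r|^2 |r'|^2 - 2 r.r' + 1) ]
            + (|r|^2 + |r'|^2)/(4 pi) - 3/(8 pi)
    """
    r = np.asarray(r, float)
    s = np.asarray(r_src, float)
    diff = r - s
    d2 = np.sum(diff * diff, axis=-1)
    if np.any(d2 == 0):
        raise ValueError("coincident evaluation and source point")
    r2 = np.sum(r * r, axis=-1)
    s2 = np.sum(s * s, axis=-1)
    dot = np.sum(r * s, axis=-1)
    img = r2 * s2 - 2.0 * dot + 1.0
    return (-(np.log(d2) + np.log(img)) / (4.0 * np.pi)
            + (r2 + s2) / (4.0 * np.pi) - 3.0 / (8.0 * np.pi))


def disk_green_gradient(r: np.ndarray, r_src: np.ndarray) -> np.ndarray:
    """Gradient of :func:`disk_green` with respect to the first argument."""
    r = np.asarray(r, float)
    s = np.asarray(r_src, float)
    diff = r - s
    d2 = np.sum(diff * diff, axis=-1, keepdims=True)
    s2 = np.sum(s * s, axis=-1, keepdims=True)
    dot = np.sum(r * s, axis=-1, keepdims=True)
    img = np.sum(r * r, axis=-1, keepdims=True) * s2 - 2.0 * dot + 1.0
    return (-(diff / d2 + (r * s2 - s) / img) / (2.0 * np.pi)
            + r / (2.0 * np.pi))


@dataclass
class GreensTable:
    """Green's function data linking boundary sources to quadrature points.

    ``points``/``weights`` define the volume quadrature over the domain
    (typically the centroids and areas of a fine auxiliary triangulation —
    a uniform pixel union leaves boundary slivers uncovered, which badly
    biases the near-boundary columns of the system matrix).

    ``values[e, k]``  = G(source_e, point_k)  (symmetric in its arguments)
    ``gradients[e, k]`` = grad_{r'} G(r', source_e) at r' = point_k
    ``source_cross[e, f]`` = G(source_e, source_f) between distinct
    electrodes (diagonal zeroed), needed for the boundary-source term of
    the collocated integral equation.
    """

    sources: np.ndarray        # (N, 2) electrode points
    points: np.ndarray         # (Q, 2) quadrature points
    weights: np.ndarray        # (Q,) quadrature weights (areas)
    values: np.ndarray         # (N, Q)
    gradients: np.ndarray      # (N, Q, 2)
    source_cross: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite Green's function values")


def greens_table_disk(electrodes: np.ndarray,
                      quadrature: TriMesh | None = None,
                      points: np.ndarray | None = None,
                      weights: np.ndarray | None = None) -> GreensTable:
    """Analytic Green's table on the unit disk.

    The quadrature is taken from a fine disk triangulation (centroids and
    areas) unless explicit points/weights are given.
    """
    src = np.asarray(electrodes, float)
    if quadrature is not None:
        points, weights = quadrature.centroids, quadrature.areas
    if points is None or weights is None:
        raise ValueError("need a quadrature mesh or explicit points/weights")
    pts = np.asarray(points, float)
    vals = disk_green(src[:, None, :], pts[None, :, :])
    grads = disk_green_gradient(pts[None, :, :], src[:, None, :])
    N = len(src)
    cross = np.zeros((N, N))
    a = np.repeat(src, N, axis=0)
    b = np.tile(src, (N, 1))
    off = ~np.eye(N, dtype=bool).ravel()
    flat = cross.reshape(-1)
    flat[off] = disk_green(a[off], b[off])
    cross = flat.reshape(N, N)
    return GreensTable(src, pts, np.asarray(weights, float), vals, grads, cross)


def _locate(mesh: TriMesh, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Containing triangle and barycentric coordinates for each point."""
    tri = mesh.triangles
    p = mesh.nodes[tri]
    # brute-force barycentric test, vectorised over elements in chunks
    idx = np.full(len(pts), -1, dtype=int)
    bary = np.zeros((len(pts), 3))
    a, b, c = p[:, 0], p[:, 1], p[:, 2]
    det = (b[:, 1] - c[:, 1]) * (a[:, 0] - c[:, 0]) + (c[:, 0] - b[:, 0]) * (a[:, 1] - c[:, 1])
    for i, pt in enumerate(pts):
        l1 = ((b[:, 1] - c[:, 1]) * (pt[0] - c[:, 0]) + (c[:, 0] - b[:, 0]) * (pt[1] - c[:, 1])) / det
        l2 = ((c[:, 1] - a[:, 1]) * (pt[0] - c[:, 0]) + (a[:, 0] - c[:, 0]) * (pt[1] - c[:, 1])) / det
        l3 = 1.0 - l1 - l2
        ok = np.flatnonzero((l1 >= -1e-10) & (l2 >= -1e-10) & (l3 >= -1e-10))
        if ok.size == 0:
            # fall back to the nearest centroid (point just outside the mesh)
            j = int(np.argmin(np.linalg.norm(mesh.centroids - pt, axis=1)))
            idx[i] = j
            pa = mesh.nodes[tri[j]]
            d = np.linalg.norm(pa - pt, axis=1)
            w = 1.0 / np.maximum(d, 1e-12)
            bary[i] = w / w.sum()
        else:
            j = int(ok[0])
            idx[i] = j
            bary[i] = (l1[j], l2[j], l3[j])
    return idx, bary


def numeric_green(mesh: TriMesh, sources: np.ndarray,
                  points: np.ndarray | None = None,
                  weights: np.ndarray | None = None) -> GreensTable:
    """FEM Neumann Green's function on an arbitrary meshed domain.

    Solves -Lap G = delta_source - 1/|Omega| with insulating boundary and a
    mean-zero gauge, one solve per source. Sources are snapped to the
    nearest mesh node (they sit on the boundary in the EIT use-case);
    values and gradients are evaluated at ``points`` from the P1
    interpolant. By default the evaluation points are the mesh's own
    element centroids weighted by element area, which doubles as the
    volume quadrature for the system-matrix assembly.
    """
    src = np.atleast_2d(np.asarray(sources, float))
    if points is None:
        points = mesh.centroids
        weights = mesh.areas
    if weights is None:
        raise ValueError("explicit points need explicit weights")
    K = _stiffness(mesh, np.ones(mesh.n_elements)).tolil()
    n = mesh.n_nodes
    areas = mesh.areas
    total = areas.sum()
    # lumped mass vector for the uniform sink and the mean-zero constraint
    mass = np.zeros(n)
    np.add.at(mass, mesh.triangles.ravel(), np.repeat(areas / 3.0, 3))
    import scipy.sparse as sp

    A = sp.vstack([
        sp.hstack([K.tocsr(), mass[:, None]]),
        sp.hstack([sp.csr_matrix(mass[None, :]), sp.csr_matrix((1, 1))]),
    ]).tocsc()
    lu = spla.splu(A)
    rhs = np.zeros((n + 1, len(src)))
    src_nodes = np.empty(len(src), dtype=int)
    for k, s in enumerate(src):
        i = int(np.argmin(np.linalg.norm(mesh.nodes - s, axis=1)))
        src_nodes[k] = i
        rhs[i, k] += 1.0
        rhs[:n, k] -= mass / total
    sol = lu.solve(rhs)[:n].T                    # (N, n) nodal G per source
    cross = sol[:, src_nodes]
    cross = 0.5 * (cross + cross.T)              # enforce symmetry
    np.fill_diagonal(cross, 0.0)
    idx, bary = _locate(mesh, np.asarray(points, float))
    tri = mesh.triangles
    vals = np.einsum("spk,pk->sp", sol[:, tri[idx]], bary)
    gx, gy = mesh.element_gradients()
    gvx = np.einsum("spk,pk->sp", sol[:, tri[idx]], gx[idx])
    gvy = np.einsum("spk,pk->sp", sol[:, tri[idx]], gy[idx])
    grads = np.stack([gvx, gvy], axis=-1)
    return GreensTable(src, np.asarray(points, float),
                       np.asarray(weights, float), vals, grads, cross)


def homogeneous_u0(r: np.ndarray, r_plus: np.ndarray, r_minus: np.ndarray,
                   I: float = 1.0, sigma0: float = 1.0,
                   green=disk_green) -> np.ndarray:
    """Homogeneous-background potential of one driven electrode pair:
    u0 = (I / sigma0) (G(r, r+) - G(r, r-))."""
    return (I / sigma0) * (green(r, r_plus) - green(r, r_minus))


# --------------------------------------------------------------------------
# system matrix
# --------------------------------------------------------------------------

@dataclass
class MoMatrix:
    """PM-MoM system matrix (n_channels x L) with its build context."""

    M: np.ndarray
    sigma0: float
    grid: PixelGrid
    params: RBFParams

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.M)):
            raise ValueError("non-finite system matrix entries")


def assemble_Mo(grid: PixelGrid, greens: GreensTable, pattern: StimPattern,
                params: RBFParams | None = None,
                sigma0: float = 1.0) -> MoMatrix:
    """Collocate the integral equation on the pixel grid.

    Entry (channel, j) is the quadrature (over the Green's table's points
    and weights) of G(r_obs, r') grad theta_j(r') . grad u0(r'), with the
    observation differenced over the channel's measurement pair and u0 the
    driven-pair background potential at the point electrodes.

    A boundary-source term supplements the volume integral: the injected
    point currents enter the domain with weight I / sigma(r_e), so when the
    log-conductivity expansion does not vanish at a drive electrode the
    channel acquires, to first order in the RBF weights,
    -(I / sigma0) G(r_obs, r_e) theta_j(r_e) per signed drive electrode.
    Without it the collocated system is badly biased whenever pixels near
    the boundary carry weight.
    """
    params = params or RBFParams(D=grid.pitch)
    L = grid.L
    qp = greens.points                                  # (Q, 2)
    w = greens.weights                                  # (Q,)
    # RBF gradient table: T[kq, j, :] = grad theta_j at quadrature point kq
    T = rbf_gradient(qp[:, None, :], grid.centers[None, :, :], params)
    Tx, Ty = T[..., 0], T[..., 1]

    I = pattern.amplitude
    theta_e = rbf_value(greens.sources[:, None, :],
                        grid.centers[None, :, :], params)   # (N, L)
    cross = greens.source_cross
    Gtab = greens.values
    grad = greens.gradients
    rows = np.empty((pattern.n_channels, L))
    row = 0
    for (p, q), meas in zip(pattern.injections, pattern.measurements):
        du0 = (I / sigma0) * (grad[p] - grad[q])             # (Q, 2)
        #  C[kq, j] = w * grad theta_j(r_kq) . grad u0(r_kq)
        C = (Tx * (w * du0[:, 0])[:, None]
             + Ty * (w * du0[:, 1])[:, None])
        for a, b in meas:
            rows[row] = (Gtab[a] - Gtab[b]) @ C
            if cross is not None:
                rows[row] -= (I / sigma0) * (
                    (cross[a, p] - cross[b, p]) * theta_e[p]
                    - (cross[a, q] - cross[b, q]) * theta_e[q])
            row += 1
    return MoMatrix(rows, float(sigma0), grid, params)


def sigma_from_coeffs(c: np.ndarray, grid: PixelGrid,
                      params: RBFParams | None = None,
                      sigma0: float = 1.0) -> np.ndarray:
    """Conductivity image sigma(rJ) = sigma0 * exp(sum_j c_j theta(rJ, rJ'))."""
    c = np.asarray(c, float)
    if c.shape != (grid.L,):
        raise ValueError("coefficient length must equal the pixel count")
    params = params or RBFParams(D=grid.pitch)
    R = rbf_value(grid.centers[:, None, :], grid.centers[None, :, :], params)
    return sigma0 * np.exp(R @ c)
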