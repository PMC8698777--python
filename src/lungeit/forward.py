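"""Complete-electrode-model finite-element forward solver.

Solves div(sigma grad u) = 0 on a triangulated 2D domain with N boundary
electrodes. Two electrode models are supported:

* ``cem``  — finite contact impedance z_l: the classical variational
  formulation with nodal potentials augmented by one voltage unknown per
  electrode.
* ``shunt`` — perfectly conducting electrodes (z_l -> 0 limit): the nodes
  under each electrode are condensed into a single voltage unknown.

The simulated admittance may be complex (sigma + j*omega*eps*eps0); all
assembly is done in complex arithmetic when needed. The gauge is fixed by
constraining the electrode voltages to sum to zero via a Lagrange
multiplier, which also makes the (symmetric) system non-singular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import ElectrodeSet, StimPattern, TriMesh

__all__ = [
    "ConductivityField",
    "VoltageFrame",
    "JacobianMatrix",
    "FEMForwardProblem",
    "assemble_and_solve",
    "frame_from_solution",
    "jacobian",
    "add_noise",
]


@dataclass
class ConductivityField:
    """Per-element complex admittance gamma = sigma + j*omega*eps*eps0."""

    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma)
        if np.any(self.gamma.real <= 0):
            raise ValueError("Re(gamma) must be positive on every element")

    @property
    def sigma(self) -> np.ndarray:
        return self.gamma.real

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.gamma)


@dataclass
class VoltageFrame:
    """One measurement frame: n_channels differential electrode voltages."""

    values: np.ndarray
    pattern: StimPattern
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.pattern.n_channels,):
            raise ValueError("frame length must equal the pattern channel count")


@dataclass
class JacobianMatrix:
    """Linearized sensitivity dU/dsigma, shape (n_channels, n_elements)."""

    J: np.ndarray
    sigma0: np.ndarray

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J)


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def _stiffness(mesh: TriMesh, gamma: np.ndarray) -> sp.csr_matrix:
    gx, gy = mesh.element_gradients()
    areas = mesh.areas
    n = mesh.n_nodes
    tri = mesh.triangles
    # local 3x3 stiffness: area * sigma * (gx gx^T + gy gy^T)
    local = (gx[:, :, None] * gx[:, None, :] + gy[:, :, None] * gy[:, None, :])
    local = local * (areas * gamma)[:, None, None]
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    return sp.csr_matrix((local.ravel(), (rows, cols)), shape=(n, n))


def _electrode_boundary_edges(mesh: TriMesh, electrodes: ElectrodeSet) -> list[np.ndarray]:
    """Boundary edges covered by each electrode arc (CEM with width > 0)."""
    loop = mesh.boundary_loop()
    pts = mesh.nodes[loop]
    c = pts.mean(axis=0)
    seg_a = pts
    seg_b = np.roll(pts, -1, axis=0)
    mid = 0.5 * (seg_a + seg_b)
    mid_ang = np.mod(np.arctan2(mid[:, 1] - c[1], mid[:, 0] - c[0]), 2 * np.pi)
    seg_len = np.linalg.norm(seg_b - seg_a, axis=1)
    out: list[np.ndarray] = []
    for ang in electrodes.angles:
        # electrode arc half-angle from its arc length at the local radius
        p = electrodes.positions[len(out)]
        radius = np.linalg.norm(p - c)
        half = 0.5 * electrodes.width / radius
        d = np.angle(np.exp(1j * (mid_ang - ang)))
        sel = np.flatnonzero(np.abs(d) <= half)
        if sel.size == 0:
            sel = np.array([int(np.argmin(np.abs(d)))])
        edges = np.column_stack([loop[sel], loop[(sel + 1) % len(loop)]])
        out.append(edges)
        _ = seg_len  # lengths recomputed per edge below
    return out


def _assemble_cem(mesh: TriMesh, gamma: np.ndarray, electrodes: ElectrodeSet):
    n = mesh.n_nodes
    N = electrodes.N
    dtype = complex if np.iscomplexobj(gamma) else float
    K = _stiffness(mesh, gamma).tolil()
    C = sp.lil_matrix((n, N), dtype=dtype)
    D = np.zeros(N, dtype=dtype)
    edges_per_el = _electrode_boundary_edges(mesh, electrodes)
    for l, edges in enumerate(edges_per_el):
        z = electrodes.contact_impedance[l]
        for (i, j) in edges:
            length = np.linalg.norm(mesh.nodes[i] - mesh.nodes[j])
            m = length / 6.0 * np.array([[2.0, 1.0], [1.0, 2.0]])
            for a, ia in enumerate((i, j)):
                for b, ib in enumerate((i, j)):
                    K[ia, ib] += m[a, b] / z
                C[ia, l] -= length / 2.0 / z
            D[l] += length / z
    # block system [[K, C], [C^T, diag(D)]] + gauge row for sum(U)=0
    top = sp.hstack([K.tocsr(), C.tocsr(), sp.csr_matrix((n, 1))])
    mid = sp.hstack([C.T.tocsr(), sp.diags(D), np.ones((N, 1))])
    bot = sp.hstack([sp.csr_matrix((1, n)), np.ones((1, N)), sp.csr_matrix((1, 1))])
    return sp.vstack([top, mid, bot]).tocsc()


def _assemble_shunt(mesh: TriMesh, gamma: np.ndarray, electrodes: ElectrodeSet):
    """Shunt model: condense the node(s) under each electrode into one DOF.

    Returns the reduced system and the mapping from original nodes to DOFs.
    Point electrodes (width 0) attach to the single nearest boundary node.
    """
    n = mesh.n_nodes
    N = electrodes.N
    edges_per_el = _electrode_boundary_edges(mesh, electrodes)
    owner = -np.ones(n, dtype=int)
    if electrodes.width == 0:
        loop = mesh.boundary_loop()
        for l, p in enumerate(electrodes.positions):
            i = loop[int(np.argmin(np.linalg.norm(mesh.nodes[loop] - p, axis=1)))]
            owner[i] = l
    else:
        for l, edges in enumerate(edges_per_el):
            owner[np.unique(edges)] = l
    free = np.flatnonzero(owner < 0)
    ndof = len(free) + N
    col = np.empty(n, dtype=int)
    col[free] = np.arange(len(free))
    col[owner >= 0] = len(free) + owner[owner >= 0]
    P = sp.csr_matrix((np.ones(n), (np.arange(n), col)), shape=(n, ndof))
    K = P.T @ _stiffness(mesh, gamma) @ P
    # gauge: electrode voltages sum to zero
    g = np.zeros((1, ndof))
    g[0, len(free):] = 1.0
    A = sp.vstack([sp.hstack([K, g.T]), sp.hstack([sp.csr_matrix(g), sp.csr_matrix((1, 1))])]).tocsc()
    return A, P, len(free)


@dataclass
class ForwardSolution:
    """Per-injection interior potentials and electrode voltages."""

    node_potentials: np.ndarray   # (n_injections, n_nodes)
    electrode_voltages: np.ndarray  # (n_injections, N)
    pattern: StimPattern


def assemble_and_solve(mesh: TriMesh, field: ConductivityField,
                       electrodes: ElectrodeSet, pattern: StimPattern,
                       model: str = "cem") -> ForwardSolution:
    """Solve the forward problem for every injection of the pattern."""
    gamma = field.gamma
    if len(gamma) != mesh.n_elements:
        raise ValueError("field length must equal the element count")
    use_complex = np.iscomplexobj(gamma)
    N = electrodes.N
    n = mesh.n_nodes
    I = pattern.amplitude
    if model == "cem":
        if np.any(electrodes.contact_impedance <= 0):
            raise ValueError("CEM requires positive contact impedances")
        A = _assemble_cem(mesh, gamma, electrodes)
        rhs = np.zeros((A.shape[0], len(pattern.injections)),
                       dtype=complex if use_complex else float)
        for k, (s, t) in enumerate(pattern.injections):
            rhs[n + s, k] = I
            rhs[n + t, k] = -I
        try:
            lu = spla.splu(A)
        except RuntimeError as exc:  # pragma: no cover - diagnostic path
            raise np.linalg.LinAlgError(f"singular CEM system: {exc}") from exc
        sol = lu.solve(rhs)
        u = sol[:n].T
        U = sol[n:n + N].T
    elif model == "shunt":
        A, P, nfree = _assemble_shunt(mesh, gamma, electrodes)
        rhs = np.zeros((A.shape[0], len(pattern.injections)),
                       dtype=complex if use_complex else float)
        for k, (s, t) in enumerate(pattern.injections):
            rhs[nfree + s, k] = I
            rhs[nfree + t, k] = -I
        try:
            lu = spla.splu(A)
        except RuntimeError as exc:  # pragma: no cover
            raise np.linalg.LinAlgError(f"singular shunt system: {exc}") from exc
        sol = lu.solve(rhs)
        u = (P @ sol[:nfree + N]).T
        U = sol[nfree:nfree + N].T
    else:
        raise ValueError("model must be 'cem' or 'shunt'")
    return ForwardSolution(np.atleast_2d(u), np.atleast_2d(U), pattern)


def frame_from_solution(solution: ForwardSolution,
                        pattern: StimPattern | None = None,
                        label: str = "") -> VoltageFrame:
    """Extract the differential channels, injection-major order."""
    pattern = pattern or solution.pattern
    U = solution.electrode_voltages
    vals = []
    for k, meas in enumerate(pattern.measurements):
        for a, b in meas:
            vals.append(U[k, a] - U[k, b])
    return VoltageFrame(np.array(vals), pattern, label=label)


# --------------------------------------------------------------------------
# Jacobian
# --------------------------------------------------------------------------

def jacobian(mesh: TriMesh, field: ConductivityField,
             electrodes: ElectrodeSet, pattern: StimPattern,
             model: str = "cem") -> JacobianMatrix:
    """Sensitivity of the differential channels to per-element conductivity.

    Entry (channel, element) = -int_elem grad u(drive) . grad u(measurement
    pair driven with unit current) dA, the adjoint-field formula for
    dimensionless electrodes. The measurement-pair fields reuse the adjacent
    solves when the pattern's measurement pairs are themselves adjacent
    pairs; otherwise dedicated solves are performed.
    """
    # collect all distinct pairs used as drives or measurement pairs
    pairs: list[tuple[int, int]] = []
    index: dict[tuple[int, int], int] = {}
    for p in pattern.injections:
        if p not in index:
            index[p] = len(pairs)
            pairs.append(p)
    for meas in pattern.measurements:
        for p in meas:
            if p not in index:
                index[p] = len(pairs)
                pairs.append(p)
    unit = StimPattern(pairs, [[] for _ in pairs], amplitude=1.0)
    sol = assemble_and_solve(mesh, field, electrodes, unit, model=model)
    gx, gy = mesh.element_gradients()
    areas = mesh.areas
    tri = mesh.triangles
    un = sol.node_potentials[:, tri]                       # (npairs, m, 3)
    ex = np.einsum("pmk,mk->pm", un, gx)
    ey = np.einsum("pmk,mk->pm", un, gy)
    rows = []
    for (k, (_, _)), meas in zip(enumerate(pattern.injections), pattern.measurements):
        d = index[pattern.injections[k]]
        for p in meas:
            m = index[p]
            rows.append(-areas * (ex[d] * ex[m] + ey[d] * ey[m]))
    J = np.vstack(rows) * pattern.amplitude
    return JacobianMatrix(J, np.asarray(field.sigma))


# --------------------------------------------------------------------------
# measurement noise
# --------------------------------------------------------------------------

def add_noise(frame: VoltageFrame, snr_db: float, seed: int | None = None) -> VoltageFrame:
    """Additive i.i.d. Gaussian channel noise at the stated SNR.

    The noise RMS is RMS(frame) * 10**(-|snr_db| / 20): the quoted decibel
    figure is the signal-to-noise power ratio, scaled against the raw frame.
    """
    v = frame.values
    if v.size == 0:
        raise ValueError("empty frame")
    if np.isinf(snr_db):
        return VoltageFrame(v.copy(), frame.pattern, label=frame.label)
    rms = float(np.sqrt(np.mean(np.abs(v) ** 2)))
    if rms == 0:
        raise ValueError("zero-RMS frame: SNR undefined")
    rng = np.random.default_rng(seed)
    scale = rms * 10.0 ** (-abs(snr_db) / 20.0)
    noise = rng.normal(0.0, scale, size=v.shape)
    if np.iscomplexobj(v):
        noise = noise + 1j * rng.normal(0.0, scale, size=v.shape)
    return VoltageFrame(v + noise, frame.pattern, label=frame.label)


# --------------------------------------------------------------------------
# bundled forward problem (used by the iterative inverse solvers)
# --------------------------------------------------------------------------

class FEMForwardProblem:
    """Mesh + electrodes + pattern bundle with solve/jacobian shortcuts."""

    def __init__(self, mesh: TriMesh, electrodes: ElectrodeSet,
                 pattern: StimPattern, model: str = "shunt"):
        self.mesh = mesh
        self.electrodes = electrodes
        self.pattern = pattern
        self.model = model

    @property
    def n_elements(self) -> int:
        return self.mesh.n_elements

    def solve(self, sigma: np.ndarray) -> np.ndarray:
        field = ConductivityField(np.asarray(sigma))
        sol = assemble_and_solve(self.mesh, field, self.electrodes,
                                 self.pattern, model=self.model)
        return frame_from_solution(sol).values

    def jacobian(self, sigma: np.ndarray) -> np.ndarray:
        return jacobian(self.mesh, ConductivityField(np.asarray(sigma)),
                        self.electrodes, self.pattern, model=self.model).J
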