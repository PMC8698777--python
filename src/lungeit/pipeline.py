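"""End-to-end study pipeline: reconstruction domain, system matrices,
method dispatch and figure-of-merit evaluation.

The reconstruction domain is a generic thorax-shaped boundary that differs
from every simulated case boundary (inverse-crime avoidance): FEM-based
methods use a coarse triangle mesh on it, the method-of-moments uses a
uniform pixel grid with point electrodes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from shapely import affinity

from .forward import FEMForwardProblem, jacobian, ConductivityField
from .mesh import (ElectrodeSet, PixelGrid, StimPattern, TriMesh,
                   adjacent_pattern, build_pixel_grid, build_polygon_mesh,
                   place_electrodes)
from .metrics import evaluate_frame, reference_image, reference_weights
from .mom import MoMatrix, RBFParams, assemble_Mo, numeric_green
from .phantom import (PhantomCase, build_phantom_case,
                      simulate_breath_sequence)
from .sbl import SBLReconstructor
from .solvers import (DifferenceOfAbsoluteReconstructor,
                      GaussNewtonReconstructor, LinearGTRReconstructor,
                      MoMRegularizedReconstructor, TVReconstructor)

__all__ = [
    "ReconSetup",
    "reconstruction_boundary",
    "build_recon_setup",
    "geometry_hash",
    "normalized_regions",
    "case_references",
    "reconstruct_frames",
    "evaluate_case",
    "METHODS",
]

#: method name -> (domain kind, default hyperparameters)
METHODS = {
    "tikhonov": ("fem", {"lam": 8e-3, "prior": "tikhonov"}),
    "laplace": ("fem", {"lam": 8e-3, "prior": "laplace"}),
    "noser": ("fem", {"lam": 8e-3, "prior": "noser"}),
    "gn": ("fem", {"lam": 8e-3, "prior": "laplace"}),
    "tv": ("fem", {"lam": 1e-6, "beta": 1e-3}),
    "diffabs": ("fem", {"lam": 5e-2, "prior": "laplace"}),
    "mom": ("mom", {"lam": 0.2, "prior": "laplace"}),
    "mom-sbl": ("mom", {"h": 4}),
}


def reconstruction_boundary(n_points: int = 160) -> np.ndarray:
    """Generic thorax-shaped reconstruction boundary, x-normalized to
    [-1, 1]; deliberately different from every simulated case boundary."""
    phi = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    x = np.sign(np.cos(phi)) * np.abs(np.cos(phi)) ** (2.0 / 2.0)
    y = 0.72 * np.sign(np.sin(phi)) * np.abs(np.sin(phi)) ** (2.0 / 2.0)
    return np.column_stack([x, y])


def geometry_hash(boundary: np.ndarray) -> str:
    return hashlib.sha256(np.round(np.asarray(boundary, float), 9).tobytes()).hexdigest()


@dataclass
class ReconSetup:
    """Everything reconstruction needs, built once per study."""

    boundary: np.ndarray
    mesh: TriMesh
    grid: PixelGrid
    electrodes: ElectrodeSet
    pattern: StimPattern
    sigma0: float
    J: np.ndarray
    Mo: MoMatrix
    problem: FEMForwardProblem
    rbf_params: RBFParams
    U1: np.ndarray = None        # homogeneous unit-background frame

    def fit_background(self, v_ref: np.ndarray) -> float:
        """Best-fit homogeneous background conductivity from an absolute
        reference frame (voltages scale as 1/sigma on a homogeneous
        domain, so the fit is a closed-form ratio)."""
        v = np.asarray(v_ref, float)
        d = float(self.U1 @ v)
        if d == 0:
            raise ValueError("reference frame orthogonal to the model frame")
        return float(self.U1 @ self.U1) / d


def build_recon_setup(n_electrodes: int = 16, fem_elements: int = 1024,
                      pixels: int = 1060, sigma0: float = 1.0,
                      green_mesh_elements: int = 3000,
                      amplitude: float = 1.0) -> ReconSetup:
    """Reconstruction domain with its FEM Jacobian and MoM system matrix.

    The Green's functions for the MoM matrix are computed numerically on an
    auxiliary fine FEM mesh of the same boundary (the domain is not a
    disk).
    """
    boundary = reconstruction_boundary()
    mesh = build_polygon_mesh(boundary, fem_elements)
    grid = build_pixel_grid(boundary, pixels)
    electrodes = place_electrodes(boundary, n_electrodes, 0.0)
    pattern = adjacent_pattern(n_electrodes, amplitude)
    problem = FEMForwardProblem(mesh, electrodes, pattern, model="shunt")
    J = jacobian(mesh, ConductivityField(np.full(mesh.n_elements, sigma0)),
                 electrodes, pattern, model="shunt").J
    gmesh = build_polygon_mesh(boundary, green_mesh_elements)
    table = numeric_green(gmesh, electrodes.positions)
    params = RBFParams(D=grid.pitch)
    Mo = assemble_Mo(grid, table, pattern, params, sigma0)
    U1 = problem.solve(np.full(mesh.n_elements, sigma0))
    return ReconSetup(boundary, mesh, grid, electrodes, pattern, sigma0,
                      J, Mo, problem, params, U1)


# --------------------------------------------------------------------------
# references
# --------------------------------------------------------------------------

def normalized_regions(case: PhantomCase, state_idx: int) -> dict:
    """True tissue polygons of one state, x-normalized to [-1, 1]."""
    st = case.states[state_idx]
    xs = st.boundary[:, 0]
    lo, hi = xs.min(), xs.max()
    c, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
    out = {}
    for k in ("left_lung", "right_lung", "vertebra", "heart", "skin",
              "muscle", "body"):
        p = st.regions[k]
        out[k] = affinity.scale(affinity.translate(p, xoff=-c),
                                xfact=1 / half, yfact=1 / half, origin=(0, 0))
    return out


def case_references(case: PhantomCase, domain: TriMesh | PixelGrid,
                    method: str = "clip"):
    """Reference difference images on a reconstruction discretization.

    Returns (delta_sigma_refs (P-1, L), regions_per_state normalized)."""
    weights, regs = [], []
    for idx in range(case.P):
        regions = normalized_regions(case, idx)
        regs.append(regions)
        weights.append(reference_weights(domain, regions, method=method))
    gam = [case.schedule.tissue_admittance(s) for s in range(1, case.P + 1)]
    ref = reference_image(weights, gam)
    return ref.delta_sigma, regs


# --------------------------------------------------------------------------
# reconstruction dispatch
# --------------------------------------------------------------------------

def reconstruct_frames(method: str, setup: ReconSetup, frames,
                       background: str | float = "auto",
                       **hyper) -> np.ndarray:
    """Difference images (states 2..P vs state 1) for one method.

    ``frames``: list of per-state VoltageFrames (absolute). FEM methods
    reconstruct on the mesh elements, MoM methods on the pixel grid.

    ``background``: the homogeneous linearization conductivity sigma_o for
    the methods whose output scale is physical (GN, difference of
    absolutes, and the MoM pair, whose exponential conductivity map is
    not scale-invariant). 'auto' (default) fits it to the first
    (reference) frame; a number uses that value; None keeps the setup's
    sigma0. The purely linear FEM methods stay on the normalized
    sigma_o = 1 Jacobian — their score metrics are amplitude-invariant
    and their default regularization weights match that convention.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; "
                         f"choose from {sorted(METHODS)}")
    kind, defaults = METHODS[method]
    kw = {**defaults, **hyper}
    V = np.array([np.asarray(f.values).real for f in frames])
    dV = V[1:] - V[0]
    if background == "auto":
        s0 = setup.fit_background(V[0])
    elif background is None:
        s0 = setup.sigma0
    else:
        s0 = float(background)
    scale = s0 / setup.sigma0
    # homogeneous rescaling: voltages ~ 1/sigma, hence Mo ~ 1/sigma
    Mo = MoMatrix(setup.Mo.M / scale, s0, setup.Mo.grid, setup.Mo.params)
    if method in ("tikhonov", "laplace", "noser"):
        est = LinearGTRReconstructor(prior=kw["prior"], lam=kw["lam"])
        est.fit(setup.J, domain=setup.mesh)
        return est.transform(dV)
    if method == "gn":
        est = GaussNewtonReconstructor(prior=kw["prior"], lam=kw["lam"],
                                       max_iter=kw.get("max_iter", 4))
        est.fit(setup.problem, sigma0=s0)
        return est.transform(dV)
    if method == "tv":
        est = TVReconstructor(lam=kw["lam"], beta=kw["beta"],
                              max_iter=kw.get("max_iter", 30))
        est.fit(setup.J, domain=setup.mesh)
        return est.transform(dV)
    if method == "diffabs":
        est = DifferenceOfAbsoluteReconstructor(prior=kw["prior"], lam=kw["lam"],
                                                max_iter=kw.get("max_iter", 5))
        est.fit(setup.problem)
        return est.transform(V)
    if method == "mom":
        est = MoMRegularizedReconstructor(prior=kw["prior"], lam=kw["lam"])
        est.fit(Mo)
        return est.transform(dV)
    est = SBLReconstructor(h=kw["h"], eps_min=kw.get("eps_min", 1e-5),
                           kappa_max=kw.get("kappa_max", 5))
    est.fit(Mo)
    return est.transform(dV)


def evaluate_case(images: np.ndarray, refs: np.ndarray, regs: list,
                  domain: TriMesh | PixelGrid, case_id: int,
                  method: str) -> list[dict]:
    """FoM rows (one per difference frame) for one case and method."""
    rows = []
    for k, (img, ref) in enumerate(zip(images, refs)):
        rep = evaluate_frame(img, ref, regs[k + 1], domain)
        row = {"case": case_id, "state": k + 2, "method": method}
        row.update(rep.as_dict())
        rows.append(row)
    return rows


def run_study(cases=(1, 2, 3), methods=("laplace", "mom-sbl"),
              snr_db: float = 50.0, seed: int = 0,
              fem_elements: int = 512, pixels: int = 400,
              phantom_elements: int = 1500) -> list[dict]:
    """Small-scale full study: simulate each case, reconstruct with each
    method, and score every difference frame. Returns FoM rows."""
    setup = build_recon_setup(fem_elements=fem_elements, pixels=pixels,
                              green_mesh_elements=max(4 * fem_elements, 2000))
    refs_cache: dict = {}
    rows: list[dict] = []
    rng = np.random.default_rng(seed)
    for cid in cases:
        case = build_phantom_case(cid, target_elements=phantom_elements,
                                  seed=int(rng.integers(2 ** 31)))
        frames = simulate_breath_sequence(case, setup.pattern, snr_db,
                                          seed=int(rng.integers(2 ** 31)))
        for method in methods:
            kind, _ = METHODS[method]
            domain = setup.mesh if kind == "fem" else setup.grid
            key = (cid, kind)
            if key not in refs_cache:
                refs_cache[key] = case_references(case, domain)
            refs, regs = refs_cache[key]
            images = reconstruct_frames(method, setup, frames)
            rows.extend(evaluate_case(images, refs, regs, domain, cid, method))
    return rows
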