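"""Synthetic dynamic-thorax phantoms.

Three subject-like 2D thoracic cases, each observed at P breath states
between end-expiration (deflated lungs) and end-inspiration (inflated).
Each state carries its own boundary (chest width grows a few percent over
the cycle), lung geometry (lung width expands 10-15%) and lung admittance.

The lung admittance follows a morphological alveolar model: a relative
lung volume F grows linearly over the inhalation,

    F_i = 3 i / (P + 1) + 3 / (P - 1) + 4,          i = 1..P,

and the conductivity is an affine function of the model shape

    sigma_l(F) = K1 [ 0.85 sb / w
                      + 0.03 si (3F/2 + 4.5) / (3F/2 + 9)^2 ] + K2,

with the two scale coefficients K1, K2 calibrated exactly to the known
end-expiration and end-inspiration conductivities (an exact 2x2 linear
solve, since the model is affine in K1, K2). Permittivity uses the
corresponding expression with an extra F^(1/3) factor in the volume term.

Tissue inhomogeneity is emulated by per-element Gaussian draws around each
tissue's mean (relative std 1% skin, 2% heart/muscle, 3% lungs);
non-positive draws are resampled so the mean is preserved. Measurement
frames are simulated on a fine per-state mesh (distinct from any
reconstruction discretization) with additive Gaussian channel noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from shapely.prepared import prep

from .forward import ConductivityField, VoltageFrame, add_noise, \
    assemble_and_solve, frame_from_solution
from .mesh import ElectrodeSet, StimPattern, TriMesh, _CASE_PRESETS, \
    _boundary_point_at_angle, build_polygon_mesh, build_thorax_boundary, \
    chest_scale, lung_scale, place_electrodes, thorax_deformation_config

__all__ = [
    "TissueTable",
    "BreathSchedule",
    "PhantomCase",
    "relative_volumes",
    "lung_conductivity_shape",
    "lung_permittivity_shape",
    "calibrate_lung_conductivity",
    "calibrate_lung_permittivity",
    "tissue_polygons",
    "label_elements",
    "assign_admittance",
    "build_phantom_case",
    "simulate_breath_sequence",
]

#: tissue order used throughout (weights, reference admittance vectors)
TISSUE_ORDER = ("left_lung", "right_lung", "vertebra", "heart", "skin", "muscle")


@dataclass
class TissueTable:
    """Mean conductivity (S/m) and omega*eps*eps0 (F Hz/m) at 100 kHz, with
    the per-tissue relative standard deviation of the element draws."""

    heart: tuple[float, float, float] = (0.215, 0.0548, 0.02)
    lung_deflated: tuple[float, float] = (0.272, 0.029)
    lung_inflated: tuple[float, float] = (0.107, 0.014)
    lung_rel_std: float = 0.03
    vertebra: tuple[float, float, float] = (0.021, 0.001, 0.0)
    skin: tuple[float, float, float] = (0.045, 0.043, 0.01)
    muscle: tuple[float, float, float] = (0.380, 0.024, 0.02)


def relative_volumes(P: int) -> np.ndarray:
    """Relative lung volumes F_1..F_P (arbitrary units), linear in the
    state index."""
    if P < 2:
        raise ValueError("need at least 2 breath states")
    i = np.arange(1, P + 1, dtype=float)
    return 3.0 * i / (P + 1) + 3.0 / (P - 1) + 4.0


def lung_conductivity_shape(F, sb: float = 0.5, w: float = 1.5,
                            si: float = 2.0):
    """Morphological part of the lung conductivity model (before the affine
    K1/K2 calibration)."""
    F = np.asarray(F, float)
    return 0.85 * sb / w + 0.03 * si * (1.5 * F + 4.5) / (1.5 * F + 9.0) ** 2


def lung_permittivity_shape(F, erb: float = 1e4, erm: float = 10.0,
                            w: float = 1.5):
    """Morphological part of the lung permittivity model."""
    F = np.asarray(F, float)
    return (0.85 * erb / w
            + 780.0 * F ** (1.0 / 3.0) * erm
            * (1.5 * F + 4.5) / (1.5 * F + 9.0) ** 2)


def _affine_calibration(q1: float, qP: float, v1: float, vP: float) -> tuple[float, float]:
    if q1 == qP:
        raise ValueError("degenerate calibration: identical endpoint volumes")
    K1 = (v1 - vP) / (q1 - qP)
    K2 = v1 - K1 * q1
    return float(K1), float(K2)


def calibrate_lung_conductivity(F1: float, FP: float, sigma_deflated: float,
                                sigma_inflated: float, sb: float = 0.5,
                                w: float = 1.5, si: float = 2.0) -> tuple[float, float]:
    """Solve the 2x2 linear system so the model matches both endpoint
    conductivities exactly."""
    if not sigma_deflated > sigma_inflated > 0:
        raise ValueError("need sigma_deflated > sigma_inflated > 0")
    q1 = float(lung_conductivity_shape(F1, sb, w, si))
    qP = float(lung_conductivity_shape(FP, sb, w, si))
    return _affine_calibration(q1, qP, sigma_deflated, sigma_inflated)


def calibrate_lung_permittivity(F1: float, FP: float, eps_deflated: float,
                                eps_inflated: float, erb: float = 1e4,
                                erm: float = 10.0, w: float = 1.5) -> tuple[float, float]:
    q1 = float(lung_permittivity_shape(F1, erb, erm, w))
    qP = float(lung_permittivity_shape(FP, erb, erm, w))
    return _affine_calibration(q1, qP, eps_deflated, eps_inflated)


@dataclass
class BreathSchedule:
    """Breath-state schedule with the calibrated lung admittance model."""

    P: int = 5
    sb: float = 0.5
    w: float = 1.5
    si: float = 2.0
    erb: float = 1e4
    erm: float = 10.0
    table: TissueTable = field(default_factory=TissueTable)

    def __post_init__(self) -> None:
        self.F = relative_volumes(self.P)
        t = self.table
        self.K1, self.K2 = calibrate_lung_conductivity(
            self.F[0], self.F[-1], t.lung_deflated[0], t.lung_inflated[0],
            self.sb, self.w, self.si)
        self.L1, self.L2 = calibrate_lung_permittivity(
            self.F[0], self.F[-1], t.lung_deflated[1], t.lung_inflated[1],
            self.erb, self.erm, self.w)

    def lung_sigma(self, state: int) -> float:
        """Mean lung conductivity (S/m) at a 1-based breath state."""
        F = self.F[state - 1]
        return self.K1 * float(lung_conductivity_shape(F, self.sb, self.w, self.si)) + self.K2

    def lung_omega_eps(self, state: int) -> float:
        """Mean lung omega*eps*eps0 (F Hz/m) at a 1-based breath state."""
        F = self.F[state - 1]
        return self.L1 * float(lung_permittivity_shape(F, self.erb, self.erm, self.w)) + self.L2

    def tissue_admittance(self, state: int, complex_valued: bool = True) -> np.ndarray:
        """Mean admittance per tissue in TISSUE_ORDER at one state."""
        t = self.table
        ls, le = self.lung_sigma(state), self.lung_omega_eps(state)
        rows = [(ls, le), (ls, le), t.vertebra[:2], t.heart[:2], t.skin[:2],
                t.muscle[:2]]
        out = np.array([s + 1j * e for s, e in rows])
        return out if complex_valued else out.real


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def _superellipse(center, rx, ry, n=2.0, n_pts=96) -> np.ndarray:
    phi = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
    x = np.sign(np.cos(phi)) * np.abs(np.cos(phi)) ** (2.0 / n)
    y = np.sign(np.sin(phi)) * np.abs(np.sin(phi)) ** (2.0 / n)
    return np.column_stack([center[0] + rx * x, center[1] + ry * y])


#: lung/organ layout per case (in state-1 normalized units)
_ORGAN_PRESETS = {
    1: dict(lung_rx=0.30, lung_ry_frac=0.58, lung_y=0.02,
            heart=((0.05, 0.22), 0.15, 0.13), vertebra=((0.0, None), 0.085)),
    2: dict(lung_rx=0.32, lung_ry_frac=0.60, lung_y=0.00,
            heart=((0.04, 0.30), 0.13, 0.11), vertebra=((0.0, None), 0.08)),
    3: dict(lung_rx=0.33, lung_ry_frac=0.62, lung_y=0.03,
            heart=((0.06, 0.24), 0.14, 0.12), vertebra=((0.0, None), 0.09)),
}
_SKIN_THICKNESS = 0.05


def tissue_polygons(case_id: int, state: int,
                    config: dict | None = None) -> dict[str, Polygon]:
    """Per-state tissue regions: disjoint shapely polygons keyed by
    TISSUE_ORDER names (muscle = body minus the others).

    The heart and vertebra are geometrically state-invariant (carved clear
    of the fully-inflated lungs so they stay disjoint at every state); the
    boundary and lungs deform with the breath schedule.
    """
    cfg = config or thorax_deformation_config()
    P = cfg["n_states"]
    if not 1 <= state <= P:
        raise ValueError(f"state must be in 1..{P}")
    shape = _CASE_PRESETS[case_id]
    org = _ORGAN_PRESETS[case_id]
    body = Polygon(build_thorax_boundary(case_id, state, cfg))

    aspect = shape["aspect"]
    sep = shape["lung_sep"]

    def lungs_at(s: int) -> tuple[Polygon, Polygon]:
        ls = lung_scale(s, cfg)
        rx = org["lung_rx"] * ls
        ry = org["lung_ry_frac"] * aspect * (1.0 + 0.4 * (ls - 1.0))
        cy = org["lung_y"]
        cx = sep + org["lung_rx"]
        ll = Polygon(_superellipse((-cx, cy), rx, ry, n=2.3))
        rl = Polygon(_superellipse((+cx, cy), rx, ry, n=2.3))
        return ll, rl

    ll, rl = lungs_at(state)
    ll_max, rl_max = lungs_at(P)

    (hx, hy), hrx, hry = org["heart"]
    heart = Polygon(_superellipse((hx, hy), hrx, hry, n=2.0))
    heart = heart.difference(ll_max).difference(rl_max)

    (vx, _), vr = org["vertebra"]
    vy = -0.72 * aspect
    vert = Polygon(_superellipse((vx, vy), vr, vr, n=2.0))
    vert = vert.difference(ll_max).difference(rl_max)

    interior = Polygon(body.exterior).buffer(-_SKIN_THICKNESS * chest_scale(state, cfg))
    skin = body.difference(interior)

    for name, poly in (("left lung", ll), ("right lung", rl)):
        if not interior.contains(poly):
            raise ValueError(f"{name} not contained in the body at state {state}")
    muscle = interior.difference(ll).difference(rl).difference(heart).difference(vert)
    return {"left_lung": ll, "right_lung": rl, "vertebra": vert,
            "heart": heart, "skin": skin, "muscle": muscle,
            "body": body, "interior": interior}


def label_elements(mesh: TriMesh, regions: dict[str, Polygon]) -> np.ndarray:
    """Tissue index (into TISSUE_ORDER) per element, by centroid lookup."""
    from shapely.geometry import Point

    cent = mesh.centroids
    labels = np.full(mesh.n_elements, TISSUE_ORDER.index("muscle"))
    order = ("left_lung", "right_lung", "vertebra", "heart", "skin")
    preps = {k: prep(regions[k]) for k in order}
    for i, c in enumerate(cent):
        p = Point(c)
        for k in order:
            if preps[k].contains(p):
                labels[i] = TISSUE_ORDER.index(k)
                break
    return labels


def assign_admittance(mesh: TriMesh, labels: np.ndarray,
                      schedule: BreathSchedule, state: int,
                      seed: int | None = None,
                      complex_valued: bool = True,
                      heterogeneous: bool = True) -> ConductivityField:
    """Per-element admittance draws around the tissue/state means.

    Real and imaginary parts are drawn with the tissue's relative std;
    non-positive conductivity draws are resampled (not truncated).
    """
    if len(labels) != mesh.n_elements:
        raise ValueError("labels must cover every element")
    t = schedule.table
    means = schedule.tissue_admittance(state)
    stds = np.array([t.lung_rel_std, t.lung_rel_std, t.vertebra[2],
                     t.heart[2], t.skin[2], t.muscle[2]])
    rng = np.random.default_rng(seed)
    sig = means.real[labels]
    eps = means.imag[labels]
    rel = stds[labels]
    if heterogeneous:
        draw = rng.normal(sig, rel * sig)
        for _ in range(100):
            bad = draw <= 0
            if not bad.any():
                break
            draw[bad] = rng.normal(sig[bad], rel[bad] * sig[bad])
        sig = draw
        eps = np.abs(rng.normal(eps, rel * eps))
    if complex_valued:
        return ConductivityField(sig + 1j * eps)
    return ConductivityField(sig)


# --------------------------------------------------------------------------
# full case assembly and simulation
# --------------------------------------------------------------------------

@dataclass
class PhantomState:
    state: int
    boundary: np.ndarray
    regions: dict
    mesh: TriMesh
    labels: np.ndarray
    field: ConductivityField
    electrodes: ElectrodeSet


@dataclass
class PhantomCase:
    case_id: int
    schedule: BreathSchedule
    config: dict
    states: list[PhantomState]

    @property
    def P(self) -> int:
        return self.schedule.P


def build_phantom_case(case_id: int, schedule: BreathSchedule | None = None,
                       config: dict | None = None,
                       target_elements: int = 1800,
                       n_electrodes: int = 16,
                       electrode_jitter: float = 0.03,
                       seed: int = 0,
                       complex_valued: bool = True,
                       heterogeneous: bool = True) -> PhantomCase:
    """Build the fine simulation model of one subject case at all states.

    Electrode angles are drawn once (3% angular jitter by default) and
    re-projected onto each state's boundary: the belt follows the chest.
    """
    schedule = schedule or BreathSchedule()
    config = config or thorax_deformation_config(n_states=schedule.P)
    rng = np.random.default_rng(seed)
    b1 = build_thorax_boundary(case_id, 1, config)
    el1 = place_electrodes(b1, n_electrodes, electrode_jitter,
                           seed=int(rng.integers(2 ** 31)))
    states = []
    for s in range(1, schedule.P + 1):
        regions = tissue_polygons(case_id, s, config)
        boundary = np.asarray(regions["body"].exterior.coords)[:-1]
        m = build_polygon_mesh(boundary, target_elements,
                               seed=int(rng.integers(2 ** 31)))
        labels = label_elements(m, regions)
        field = assign_admittance(m, labels, schedule, s,
                                  seed=int(rng.integers(2 ** 31)),
                                  complex_valued=complex_valued,
                                  heterogeneous=heterogeneous)
        pos = _boundary_point_at_angle(boundary, el1.angles)
        el = ElectrodeSet(el1.angles.copy(), pos, width=el1.width,
                          contact_impedance=el1.contact_impedance)
        states.append(PhantomState(s, boundary, regions, m, labels, field, el))
    return PhantomCase(case_id, schedule, config, states)


def simulate_breath_sequence(case: PhantomCase, pattern: StimPattern,
                             snr_db: float = 50.0, seed: int = 0,
                             model: str = "shunt") -> list[VoltageFrame]:
    """CEM/shunt forward solve per state on the fine per-state mesh, with
    additive channel noise; returns one frame per breath state."""
    rng = np.random.default_rng(seed)
    frames = []
    for st in case.states:
        sol = assemble_and_solve(st.mesh, st.field, st.electrodes, pattern,
                                 model=model)
        frame = frame_from_solution(sol, label=f"case{case.case_id}_state{st.state}")
        if np.isfinite(snr_db):
            frame = add_noise(frame, snr_db, seed=int(rng.integers(2 ** 31)))
        frames.append(frame)
    return frames
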