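"""Geometry, meshes, electrodes and measurement patterns.

Two discretizations coexist in a time-difference EIT study: a *fine*
simulation mesh (where the phantom lives) and a coarser *reconstruction*
discretization, either a triangular mesh for FEM-based solvers or a uniform
pixel grid for the method-of-moments system.  Keeping their boundaries and
meshes distinct is what protects against the inverse crime.

All boundaries are x-normalized so the chest width spans [-1, 1] in
arbitrary units at the reference (end-expiration) state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay
from shapely.geometry import Point, Polygon

__all__ = [
    "TriMesh",
    "PixelGrid",
    "ElectrodeSet",
    "StimPattern",
    "build_disk_mesh",
    "build_polygon_mesh",
    "build_thorax_boundary",
    "place_electrodes",
    "adjacent_pattern",
    "build_pixel_grid",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class TriMesh:
    """Linear triangle mesh: ``nodes`` (n, 2), ``triangles`` (m, 3) indices."""

    nodes: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 2:
            raise ValueError("nodes must be (n, 2)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        a = self.areas
        if np.any(a <= 0):
            # enforce positive orientation, then re-check for degenerate elements
            bad = a <= 0
            self.triangles[bad] = self.triangles[bad][:, ::-1]
            if np.any(self.areas <= 1e-14 * max(1.0, float(np.max(np.abs(self.nodes))))):
                raise ValueError("mesh contains degenerate elements")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    @property
    def areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        u = p[:, 1] - p[:, 0]
        v = p[:, 2] - p[:, 0]
        return 0.5 * (u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])

    @property
    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    @property
    def boundary_edges(self) -> np.ndarray:
        """Edges belonging to exactly one triangle, as (k, 2) node pairs."""
        e = np.vstack([self.triangles[:, [0, 1]],
                       self.triangles[:, [1, 2]],
                       self.triangles[:, [2, 0]]])
        key = np.sort(e, axis=1)
        _, idx, cnt = np.unique(key, axis=0, return_index=True, return_counts=True)
        return e[idx[cnt == 1]]

    def boundary_loop(self) -> np.ndarray:
        """Boundary node indices ordered along the single closed loop."""
        edges = self.boundary_edges
        nxt = dict(map(tuple, edges))
        start = edges[0, 0]
        loop = [start]
        cur = nxt[start]
        while cur != start:
            loop.append(cur)
            if cur not in nxt or len(loop) > len(edges) + 1:
                raise ValueError("boundary does not form one closed loop")
            cur = nxt[cur]
        if len(loop) != len(edges):
            raise ValueError("boundary does not form one closed loop")
        return np.array(loop, dtype=np.int64)

    def element_gradients(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-element P1 shape-function gradients.

        Returns (gx, gy), each (m, 3): the constant gradient of each local
        basis function on each triangle.
        """
        p = self.nodes[self.triangles]
        x, y = p[..., 0], p[..., 1]
        det = 2.0 * self.areas
        b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
        c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
        return b / det[:, None], c / det[:, None]


@dataclass
class PixelGrid:
    """Uniform square pixel lattice clipped to a body boundary polygon."""

    centers: np.ndarray           # (L, 2)
    pitch: float
    rows: np.ndarray              # (L,) row index of each pixel
    cols: np.ndarray              # (L,) column index
    boundary: np.ndarray          # (nb, 2) closed body polygon (last != first)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if len(self.rows) != self.L or len(self.cols) != self.L:
            raise ValueError("index map length mismatch")

    @property
    def L(self) -> int:
        return self.centers.shape[0]

    @property
    def pixel_area(self) -> float:
        return self.pitch ** 2

    def polygon(self) -> Polygon:
        return Polygon(self.boundary)


@dataclass
class ElectrodeSet:
    """Electrodes on the domain boundary.

    ``angles`` are polar angles about the boundary centroid, strictly
    increasing modulo 2*pi; ``positions`` the corresponding boundary points.
    ``width`` is the electrode arc length (0 for point electrodes) and
    ``contact_impedance`` the per-electrode z_l of the complete electrode
    model.
    """

    angles: np.ndarray
    positions: np.ndarray
    width: float = 0.0
    contact_impedance: np.ndarray | float = 1e-3

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.N < 4:
            raise ValueError("need at least 4 electrodes")
        if self.width < 0:
            raise ValueError("width must be non-negative")
        d = np.diff(np.unwrap(self.angles))
        if np.any(d <= 0):
            raise ValueError("electrode angles must be strictly ordered")
        self.contact_impedance = np.broadcast_to(
            np.asarray(self.contact_impedance, dtype=float), (self.N,)).copy()

    @property
    def N(self) -> int:
        return len(self.angles)


@dataclass
class StimPattern:
    """Current injections and their voltage measurement pairs.

    ``injections``: list of (source, sink) electrode indices.
    ``measurements``: per injection, list of (positive, negative) electrode
    pairs. The channel value is U[pos] - U[neg]. Channels are ordered
    injection-major.
    """

    injections: list[tuple[int, int]]
    measurements: list[list[tuple[int, int]]]
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if len(self.injections) != len(self.measurements):
            raise ValueError("one measurement list per injection required")
        for (s, k), meas in zip(self.injections, self.measurements):
            for a, b in meas:
                if {a, b} & {s, k}:
                    raise ValueError("measurement pair touches a drive electrode")

    @property
    def n_channels(self) -> int:
        return sum(len(m) for m in self.measurements)

    def channel_index(self) -> list[tuple[int, int, int, int]]:
        """Flat (source, sink, meas+, meas-) tuple per channel."""
        out = []
        for (s, k), meas in zip(self.injections, self.measurements):
            out.extend((s, k, a, b) for a, b in meas)
        return out


# --------------------------------------------------------------------------
# mesh generation
# --------------------------------------------------------------------------

def _hex_lattice(bbox: tuple[float, float, float, float], spacing: float) -> np.ndarray:
    x0, y0, x1, y1 = bbox
    dy = spacing * np.sqrt(3.0) / 2.0
    ys = np.arange(y0, y1 + dy, dy)
    pts = []
    for i, y in enumerate(ys):
        off = 0.5 * spacing if i % 2 else 0.0
        xs = np.arange(x0 + off, x1 + spacing, spacing)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    return np.vstack(pts)


def build_polygon_mesh(boundary: np.ndarray, target_element_count: int,
                       seed: int | None = None) -> TriMesh:
    """Delaunay-triangulate the interior of a simple closed polygon.

    Boundary nodes are resampled at the target spacing; interior nodes come
    from a hexagonal lattice kept clear of the boundary, so triangle quality
    is near-uniform. Element count lands within ~±25% of the target.
    """
    boundary = np.asarray(boundary, dtype=float)
    poly = Polygon(boundary)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("boundary polygon must be simple and positively oriented")
    if target_element_count < 16:
        raise ValueError("target_element_count must be >= 16")
    area = poly.area
    # ~2 triangles per interior lattice point (hex cell area sqrt(3)/2 s^2)
    s = float(np.sqrt(4.0 * area / (np.sqrt(3.0) * target_element_count)))

    ring = poly.exterior
    n_b = max(8, int(np.ceil(ring.length / s)))
    t = np.linspace(0.0, ring.length, n_b, endpoint=False)
    bnodes = np.array([ring.interpolate(ti).coords[0] for ti in t])

    lat = _hex_lattice(poly.bounds, s)
    inner = poly.buffer(-0.55 * s)
    if inner.is_empty:
        keep = np.zeros(len(lat), dtype=bool)
    else:
        keep = np.array([inner.contains(Point(p)) for p in lat])
    nodes = np.vstack([bnodes, lat[keep]])

    tri = Delaunay(nodes)
    cent = nodes[tri.simplices].mean(axis=1)
    # drop triangles outside non-convex boundaries
    inside = np.array([poly.contains(Point(c)) for c in cent])
    return TriMesh(nodes, tri.simplices[inside])


def build_disk_mesh(radius: float, target_element_count: int) -> TriMesh:
    """Mesh the disk of the given radius, used for canonical-geometry oracles."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    boundary = radius * np.column_stack([np.cos(th), np.sin(th)])
    mesh = build_polygon_mesh(boundary, target_element_count)
    # snap boundary nodes exactly onto the circle
    loop = mesh.boundary_loop()
    p = mesh.nodes[loop]
    r = np.linalg.norm(p, axis=1)
    mesh.nodes[loop] = p * (radius / r)[:, None]
    return mesh


# --------------------------------------------------------------------------
# thorax boundary family
# --------------------------------------------------------------------------

#: per-case shape presets: (aspect ratio b/a, superellipse exponent,
#: posterior-flattening depth, lung half-separation as fraction of width)
_CASE_PRESETS = {
    1: dict(aspect=0.70, exponent=2.4, flat=0.10, lung_sep=0.24),
    2: dict(aspect=0.75, exponent=2.2, flat=0.08, lung_sep=0.15),
    3: dict(aspect=0.65, exponent=2.6, flat=0.12, lung_sep=0.26),
}


def thorax_deformation_config(chest_total: float = 0.065,
                              lung_total: float = 0.125,
                              n_states: int = 5) -> dict:
    """Linear deformation schedule across breath states.

    ``chest_total``: fractional chest-width increase from state 1 to state P
    (physiological range 5-8%). ``lung_total``: fractional lung-width
    expansion (range 10-15%).
    """
    if not (0 < chest_total < 0.5 and 0 < lung_total < 0.5):
        raise ValueError("implausible deformation totals")
    return dict(chest_total=float(chest_total), lung_total=float(lung_total),
                n_states=int(n_states))


def chest_scale(state: int, config: dict) -> float:
    P = config["n_states"]
    if not 1 <= state <= P:
        raise ValueError(f"state must be in 1..{P}")
    return 1.0 + config["chest_total"] * (state - 1) / (P - 1)


def lung_scale(state: int, config: dict) -> float:
    P = config["n_states"]
    if not 1 <= state <= P:
        raise ValueError(f"state must be in 1..{P}")
    return 1.0 + config["lung_total"] * (state - 1) / (P - 1)


def build_thorax_boundary(case_id: int, state: int = 1,
                          deformation_config: dict | None = None,
                          n_points: int = 180) -> np.ndarray:
    """Smooth closed thorax-like boundary for one subject case and state.

    A superellipse with a Gaussian posterior flattening, x-normalized to
    [-1, 1] at state 1; later states scale the width by the configured
    linear chest schedule.
    """
    if case_id not in _CASE_PRESETS:
        raise ValueError("case_id must be 1, 2 or 3")
    cfg = deformation_config or thorax_deformation_config()
    p = _CASE_PRESETS[case_id]
    phi = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    n = p["exponent"]
    x = np.sign(np.cos(phi)) * np.abs(np.cos(phi)) ** (2.0 / n)
    y = p["aspect"] * np.sign(np.sin(phi)) * np.abs(np.sin(phi)) ** (2.0 / n)
    # posterior (back) flattening: radial Gaussian dip centred at phi=3pi/2
    d = np.angle(np.exp(1j * (phi - 1.5 * np.pi)))
    dip = p["flat"] * np.exp(-(d / 0.8) ** 2)
    r = 1.0 - dip
    pts = np.column_stack([x * r, y * r])
    # x-normalize the state-1 shape to [-1, 1]
    half_w = 0.5 * (pts[:, 0].max() - pts[:, 0].min())
    xc = 0.5 * (pts[:, 0].max() + pts[:, 0].min())
    pts[:, 0] = (pts[:, 0] - xc) / half_w
    pts[:, 1] /= half_w
    pts *= chest_scale(state, cfg)
    if not Polygon(pts).is_valid:
        raise ValueError("self-intersecting thorax configuration")
    return pts


# --------------------------------------------------------------------------
# electrodes and patterns
# --------------------------------------------------------------------------

def _boundary_point_at_angle(boundary: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Intersect rays at polar angles ``theta`` (about the centroid) with a
    closed polygon boundary."""
    poly = Polygon(boundary)
    c = np.array(poly.centroid.coords[0])
    verts = boundary - c
    ang = np.unwrap(np.arctan2(verts[:, 1], verts[:, 0]))
    if ang[-1] < ang[0]:       # enforce CCW parameterisation
        verts = verts[::-1]
        ang = np.unwrap(np.arctan2(verts[:, 1], verts[:, 0]))
    ang = ang - 2 * np.pi * np.floor(ang[0] / (2 * np.pi))
    ang_ext = np.concatenate([ang, [ang[0] + 2 * np.pi]])
    r = np.linalg.norm(verts, axis=1)
    r_ext = np.concatenate([r, [r[0]]])
    th = np.mod(theta - ang_ext[0], 2 * np.pi) + ang_ext[0]
    rr = np.interp(th, ang_ext, r_ext)
    return c + np.column_stack([rr * np.cos(theta), rr * np.sin(theta)])


def place_electrodes(boundary: np.ndarray, N: int = 16,
                     angle_jitter_relative_std: float = 0.0,
                     seed: int | None = None,
                     width: float = 0.0,
                     contact_impedance: float = 1e-3,
                     max_retries: int = 50) -> ElectrodeSet:
    """Place N electrodes equally spaced in boundary angle, with optional
    zero-mean Gaussian angular jitter (std = fraction of the spacing).

    Jitter draws that would swap the electrode order are resampled a bounded
    number of times before raising.
    """
    if N < 4:
        raise ValueError("need at least 4 electrodes")
    base = 2 * np.pi * np.arange(N) / N
    rng = np.random.default_rng(seed)
    spacing = 2 * np.pi / N
    for _ in range(max_retries):
        jitter = (rng.normal(0.0, angle_jitter_relative_std * spacing, size=N)
                  if angle_jitter_relative_std > 0 else np.zeros(N))
        angles = base + jitter
        if np.all(np.diff(angles) > 0) and angles[-1] - angles[0] < 2 * np.pi:
            pos = _boundary_point_at_angle(np.asarray(boundary, float), angles)
            return ElectrodeSet(angles, pos, width=width,
                                contact_impedance=contact_impedance)
    raise RuntimeError("could not draw order-preserving electrode jitter")


def adjacent_pattern(N: int, amplitude: float = 1.0) -> StimPattern:
    """Adjacent (skip-0) protocol: drive neighbouring pairs (l, l+1 mod N),
    measure on every neighbouring pair not touching a drive electrode.

    For point electrodes this yields N - 3 measurements per injection and
    N * (N - 3) channels per frame (13 and 208 for N = 16).
    """
    if N < 4:
        raise ValueError("need at least 4 electrodes")
    injections, measurements = [], []
    for l in range(N):
        drive = (l, (l + 1) % N)
        injections.append(drive)
        meas = []
        for k in range(N):
            pair = (k, (k + 1) % N)
            if set(pair) & set(drive):
                continue
            meas.append(pair)
        measurements.append(meas)
    return StimPattern(injections, measurements, amplitude=float(amplitude))


# --------------------------------------------------------------------------
# pixel grid
# --------------------------------------------------------------------------

def build_pixel_grid(boundary: np.ndarray, target_pixel_count: int,
                     max_iter: int = 12, margin: float = 0.5) -> PixelGrid:
    """Uniform square lattice of pixel centers strictly inside the boundary.

    Centers are kept ``margin`` pitches clear of the boundary (so each
    pixel's square is essentially interior, which also keeps the
    collocation basis functions resolvable). The pitch is iterated so the
    interior pixel count lands within ±10% of the target.
    """
    boundary = np.asarray(boundary, dtype=float)
    poly = Polygon(boundary)
    if not poly.is_valid:
        raise ValueError("boundary must be a simple closed polygon")
    if target_pixel_count < 9:
        raise ValueError("target too small to tile the interior")
    x0, y0, x1, y1 = poly.bounds
    s = float(np.sqrt(poly.area / target_pixel_count))
    lo, hi = 0.1, 1.1
    for _ in range(max_iter):
        xs = np.arange(x0 + s / 2, x1, s)
        ys = np.arange(y0 + s / 2, y1, s)
        cx, cy = np.meshgrid(xs, ys, indexing="xy")
        rows, cols = np.meshgrid(np.arange(len(ys)), np.arange(len(xs)),
                                 indexing="ij")
        pts = np.column_stack([cx.ravel(), cy.ravel()])
        region = poly.buffer(-margin * s) if margin > 0 else poly
        inside = np.array([region.contains(Point(p)) for p in pts])
        L = int(inside.sum())
        if abs(L - target_pixel_count) <= lo * target_pixel_count:
            order = np.lexsort((pts[inside][:, 0], -pts[inside][:, 1]))
            return PixelGrid(pts[inside][order], s,
                             rows.ravel()[inside][order],
                             cols.ravel()[inside][order], boundary)
        if L == 0:
            raise ValueError("target too small to tile the interior")
        s *= np.sqrt(L / target_pixel_count)
        s = min(max(s, 1e-6), hi * np.sqrt(poly.area))
    raise RuntimeError("pixel grid did not converge to the target count")
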