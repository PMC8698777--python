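"""Reference-image extraction and figures of merit.

A reconstruction is scored against a "true" image painted on the same
reconstruction discretization: per-pixel tissue area fractions (weights)
times the per-state mean tissue admittances, differenced against the
end-expiration frame. Both geometries are x-normalized to [-1, 1] before
clipping so that differently shaped simulation and reconstruction domains
can be compared.

Eight figures of merit are produced per reconstructed frame: the GREIT-style
target amplitude (TA), position error (PE, split per lung), shape
deformation (SD), resolution (RES) and ringing (RNG), plus the Pearson
correlation coefficient (CC), RMSE and the full-reference metric (global
GFR and per-lung FR). Lungs are detected in a reconstruction by
thresholding at -1/4 of the maximum absolute amplitude, and the left/right
inclusions are separated by the x = 0 line.

Two printed-versus-prose ambiguities are exposed as conventions rather than
silently chosen: ``sd_convention`` ('printed': out-of-lung over in-lung
area ratio; 'fraction': out-of-lung over total) and ``rng_convention``
('opposite': out-of-lung amplitude of sign opposite to the dominant in-lung
sign, the stated intent; 'printed': negative out-of-lung amplitude as the
formula reads).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon, box

from .mesh import PixelGrid, TriMesh
from .phantom import TISSUE_ORDER

__all__ = [
    "WeightTable",
    "ReferenceImage",
    "FoMReport",
    "x_normalize",
    "reference_weights",
    "reference_image",
    "filter_image",
    "fom_ta",
    "fom_pe",
    "fom_sd",
    "fom_res",
    "fom_rng",
    "fom_cc",
    "fom_rmse",
    "fom_fr",
    "evaluate_frame",
]


@dataclass
class WeightTable:
    """Per-pixel tissue area fractions, columns in TISSUE_ORDER."""

    w: np.ndarray        # (L, 6)

    def __post_init__(self) -> None:
        if self.w.ndim != 2 or self.w.shape[1] != len(TISSUE_ORDER):
            raise ValueError("weights must be (L, 6)")
        if np.any(self.w < -1e-9) or np.any(self.w > 1 + 1e-9):
            raise ValueError("weights must lie in [0, 1]")


@dataclass
class ReferenceImage:
    """Absolute per-state reference admittances and their differences."""

    gamma_abs: np.ndarray        # (P, L) complex absolute images
    states: int

    @property
    def delta(self) -> np.ndarray:
        """(P-1, L) complex difference images, state l+1 minus state 1."""
        return self.gamma_abs[1:] - self.gamma_abs[0]

    @property
    def delta_sigma(self) -> np.ndarray:
        return self.delta.real


@dataclass
class FoMReport:
    TA: float
    PE: float
    PE_LL: float
    PE_RL: float
    SD: float
    RES: float
    RNG: float
    CC: float
    RMSE: float
    GFR: float
    FR_LL: float
    FR_RL: float

    def as_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in
                ("TA", "PE", "PE_LL", "PE_RL", "SD", "RES", "RNG", "CC",
                 "RMSE", "GFR", "FR_LL", "FR_RL")}


def x_normalize(points: np.ndarray, bounds: tuple[float, float] | None = None):
    """Scale and shift so the x-extent maps onto [-1, 1] (y scales by the
    same factor, preserving aspect)."""
    points = np.asarray(points, float)
    if bounds is None:
        lo, hi = points[:, 0].min(), points[:, 0].max()
    else:
        lo, hi = bounds
    c, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
    out = points.copy()
    out[:, 0] = (out[:, 0] - c) / half
    out[:, 1] = out[:, 1] / half
    return out


def _cells(domain: TriMesh | PixelGrid) -> tuple[list[Polygon], np.ndarray, np.ndarray]:
    """Per-pixel/element polygons, centers and areas of a discretization."""
    if isinstance(domain, PixelGrid):
        half = domain.pitch / 2.0
        polys = [box(x - half, y - half, x + half, y + half)
                 for x, y in domain.centers]
        return polys, domain.centers, np.full(domain.L, domain.pixel_area)
    if isinstance(domain, TriMesh):
        polys = [Polygon(domain.nodes[t]) for t in domain.triangles]
        return polys, domain.centroids, domain.areas
    raise TypeError("domain must be a TriMesh or PixelGrid")


def reference_weights(domain: TriMesh | PixelGrid,
                      regions: dict[str, Polygon],
                      method: str = "clip",
                      subsamples: int = 16) -> WeightTable:
    """Per-pixel area fractions of the six tissues.

    ``regions`` holds the *true* tissue polygons (already x-normalized to
    the reconstruction frame). Muscle takes the in-body remainder.
    ``method='clip'`` uses exact polygon clipping; ``'sample'`` uses an
    n x n sub-sample per cell.
    """
    for k in ("left_lung", "right_lung", "vertebra", "heart", "skin"):
        if not regions[k].is_valid:
            raise ValueError(f"invalid tissue polygon {k!r}")
    polys, centers, areas = _cells(domain)
    body = regions.get("body")
    L = len(polys)
    W = np.zeros((L, len(TISSUE_ORDER)))
    organ_keys = ("left_lung", "right_lung", "vertebra", "heart", "skin")
    if method == "clip":
        for i, cell in enumerate(polys):
            a = cell.area
            used = 0.0
            for j, k in enumerate(organ_keys):
                frac = cell.intersection(regions[k]).area / a
                W[i, j] = frac
                used += frac
            inb = cell.intersection(body).area / a if body is not None else 1.0
            W[i, 5] = max(inb - used, 0.0)
    elif method == "sample":
        t = (np.arange(subsamples) + 0.5) / subsamples
        from shapely.prepared import prep
        preps = [prep(regions[k]) for k in organ_keys]
        bprep = prep(body) if body is not None else None
        from shapely.geometry import Point
        for i, cell in enumerate(polys):
            x0, y0, x1, y1 = cell.bounds
            xs = x0 + t * (x1 - x0)
            ys = y0 + t * (y1 - y0)
            pts = [Point(x, y) for x in xs for y in ys
                   if cell.contains(Point(x, y))]
            if not pts:
                continue
            n = len(pts)
            hit = np.zeros(len(TISSUE_ORDER))
            for p in pts:
                for j, pr in enumerate(preps):
                    if pr.contains(p):
                        hit[j] += 1
                        break
                else:
                    if bprep is None or bprep.contains(p):
                        hit[5] += 1
            W[i] = hit / n
    else:
        raise ValueError("method must be 'clip' or 'sample'")
    return WeightTable(W)


def reference_image(weights_per_state: list[WeightTable],
                    admittance_per_state: list[np.ndarray]) -> ReferenceImage:
    """Absolute reference image per state: gamma_r = W @ gamma_t."""
    if len(weights_per_state) != len(admittance_per_state):
        raise ValueError("need one admittance vector per state")
    imgs = [w.w @ np.asarray(g) for w, g in
            zip(weights_per_state, admittance_per_state)]
    return ReferenceImage(np.array(imgs), len(imgs))


# --------------------------------------------------------------------------
# figures of merit
# --------------------------------------------------------------------------

def filter_image(ds: np.ndarray) -> np.ndarray:
    """Binary lung mask: pixels at or below -1/4 of the maximum absolute
    amplitude (air-filling makes the lungs *less* conductive)."""
    ds = np.asarray(ds, float)
    m = np.max(np.abs(ds))
    if m == 0:
        raise ValueError("all-zero image: threshold undefined")
    return (ds <= -0.25 * m).astype(float)


def fom_ta(ds: np.ndarray) -> float:
    """Normalized amplitude summary sum(ds) / max|ds|."""
    ds = np.asarray(ds).real
    m = np.max(np.abs(ds))
    if m == 0:
        raise ValueError("all-zero image")
    return float(np.sum(ds) / m)


def _side_masks(centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return centers[:, 0] < 0.0, centers[:, 0] >= 0.0


def _lung_sides(regions: dict[str, Polygon]) -> tuple[Polygon, Polygon]:
    """(left-of-axis lung, right-of-axis lung) by centroid x."""
    ll, rl = regions["left_lung"], regions["right_lung"]
    return (ll, rl) if ll.centroid.x < rl.centroid.x else (rl, ll)


def fom_pe(xf: np.ndarray, regions: dict[str, Polygon],
           domain: TriMesh | PixelGrid) -> tuple[float, float, float]:
    """Position error: distance between the area-weighted centroid of the
    filtered mask on each side of x = 0 and the true lung centroid."""
    _, centers, areas = _cells(domain)
    lungL, lungR = _lung_sides(regions)
    left, right = _side_masks(centers)
    out = []
    for side, lung in ((left, lungL), (right, lungR)):
        w = xf * side * areas
        if w.sum() == 0:
            out.append(np.nan)
            continue
        c = (centers * w[:, None]).sum(axis=0) / w.sum()
        t = np.array([lung.centroid.x, lung.centroid.y])
        out.append(float(np.linalg.norm(c - t)))
    pe_ll, pe_rl = out
    return float(pe_ll + pe_rl), pe_ll, pe_rl


def _in_lung(centers: np.ndarray, lung: Polygon) -> np.ndarray:
    from shapely.prepared import prep
    from shapely.geometry import Point
    pr = prep(lung)
    return np.array([pr.contains(Point(c)) for c in centers])


def fom_sd(xf: np.ndarray, regions: dict[str, Polygon],
           domain: TriMesh | PixelGrid, convention: str = "printed") -> float:
    """Shape deformation: filtered area escaping the true lungs.

    'printed': (out-of-lung filtered area) / (in-lung filtered area);
    'fraction': out-of-lung over total filtered area.
    """
    _, centers, areas = _cells(domain)
    lungL, lungR = _lung_sides(regions)
    left, right = _side_masks(centers)
    inside = out = 0.0
    for side, lung in ((left, lungL), (right, lungR)):
        w = xf * side * areas
        inl = _in_lung(centers, lung)
        inside += float(w[inl].sum())
        out += float(w[~inl].sum())
    if convention == "printed":
        if inside == 0:
            return float("nan")
        return out / inside
    if convention == "fraction":
        tot = inside + out
        return out / tot if tot > 0 else float("nan")
    raise ValueError("convention must be 'printed' or 'fraction'")


def fom_res(xf: np.ndarray, domain: TriMesh | PixelGrid,
            regions: dict[str, Polygon] | None = None) -> float:
    """Resolution: filtered lung area over the domain area."""
    _, centers, areas = _cells(domain)
    Ao = float(areas.sum())
    return float((xf * areas).sum() / Ao)


def fom_rng(ds: np.ndarray, regions: dict[str, Polygon],
            domain: TriMesh | PixelGrid, convention: str = "opposite") -> float:
    """Ringing: spurious amplitude outside the lungs relative to the lung
    response."""
    ds = np.asarray(ds).real
    _, centers, _ = _cells(domain)
    lungL, lungR = _lung_sides(regions)
    in_lungs = _in_lung(centers, lungL) | _in_lung(centers, lungR)
    lung_sum = ds[in_lungs].sum()
    if lung_sum == 0:
        return float("nan")
    if convention == "opposite":
        s = np.sign(lung_sum)
        opp = ds[~in_lungs]
        num = np.abs(opp[np.sign(opp) == -s]).sum()
        den = np.abs(ds[in_lungs][np.sign(ds[in_lungs]) == s]).sum()
        return float(num / den) if den > 0 else float("nan")
    if convention == "printed":
        outside = ds[~in_lungs]
        num = outside[outside < 0].sum()
        return float(num / lung_sum)
    raise ValueError("convention must be 'opposite' or 'printed'")


def fom_cc(ds: np.ndarray, ds_ref: np.ndarray) -> float:
    """Pearson correlation between reconstruction and reference."""
    a = np.asarray(ds).real
    b = np.asarray(ds_ref).real
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance image: CC undefined")
    return float(np.corrcoef(a, b)[0, 1])


def fom_rmse(ds: np.ndarray, ds_ref: np.ndarray) -> float:
    a = np.asarray(ds).real
    b = np.asarray(ds_ref).real
    if a.shape != b.shape:
        raise ValueError("image length mismatch")
    return float(np.sqrt(np.mean((b - a) ** 2)))


def fom_fr(ds: np.ndarray, ds_ref: np.ndarray,
           regions: dict[str, Polygon] | None = None,
           domain: TriMesh | PixelGrid | None = None
           ) -> tuple[float, float, float]:
    """Full-reference metric on max-normalized images:
    GFR = 0.5 sum |EDref - EDtest|, with per-lung restrictions."""
    a = np.asarray(ds).real
    b = np.asarray(ds_ref).real
    ma, mb = np.max(np.abs(a)), np.max(np.abs(b))
    if ma == 0 or mb == 0:
        raise ValueError("all-zero image: FR undefined")
    ta, tb = a / ma, b / mb
    gfr = 0.5 * float(np.abs(tb - ta).sum())
    fr_ll = fr_rl = float("nan")
    if regions is not None and domain is not None:
        _, centers, _ = _cells(domain)
        lungL, lungR = _lung_sides(regions)
        mL, mR = _in_lung(centers, lungL), _in_lung(centers, lungR)
        fr_ll = 0.5 * float(np.abs(tb[mL] - ta[mL]).sum())
        fr_rl = 0.5 * float(np.abs(tb[mR] - ta[mR]).sum())
    return gfr, fr_ll, fr_rl


def evaluate_frame(ds: np.ndarray, ds_ref: np.ndarray,
                   regions: dict[str, Polygon],
                   domain: TriMesh | PixelGrid,
                   sd_convention: str = "printed",
                   rng_convention: str = "opposite") -> FoMReport:
    """All figures of merit for one reconstructed difference image."""
    ds = np.asarray(ds).real
    xf = filter_image(ds)
    pe, pe_ll, pe_rl = fom_pe(xf, regions, domain)
    gfr, fr_ll, fr_rl = fom_fr(ds, ds_ref, regions, domain)
    return FoMReport(
        TA=fom_ta(ds),
        PE=pe, PE_LL=pe_ll, PE_RL=pe_rl,
        SD=fom_sd(xf, regions, domain, sd_convention),
        RES=fom_res(xf, domain),
        RNG=fom_rng(ds, regions, domain, rng_convention),
        CC=fom_cc(ds, ds_ref),
        RMSE=fom_rmse(ds, ds_ref),
        GFR=gfr, FR_LL=fr_ll, FR_RL=fr_rl,
    )
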