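"""Centerline extraction and morphometry of lumen surfaces.

All per-slice and whole-lumen quantities used in longitudinal follow-up of a
stented dissected aorta: centerline (seeded centroid-marching), tortuosity
1 - d/l, Menger curvature profiles, perpendicular cross-section slicing at a
fixed arc-length interval (default 1.0 mm) with per-slice metrics (area,
circumference, equivalent/transverse/longitudinal diameter, aspect ratio),
enclosed lumen volume, and stent-graft diameter oversizing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from shapely.geometry import Point, Polygon

from ._geometry import TriangleQuery, polygon_area_centroid_2d, plane_basis, to_plane_coords
from .mesh_io import SurfaceMesh

log = logging.getLogger("aortamorph")

DEFAULT_SLICE_INTERVAL_MM = 1.0
DEFAULT_CURVATURE_WINDOW_MM = 5.0


class MeshIntegrityError(ValueError):
    """Raised when an operation requires a closed, watertight surface."""


class BranchAmbiguityError(RuntimeError):
    """Centerline marching found two comparable continuations; add an
    intermediate seed between the ambiguous stations."""


# ---------------------------------------------------------------------------
# centerline container
# ---------------------------------------------------------------------------

@dataclass
class Centerline:
    """Ordered polyline (mm) with arc-length parameterization.

    ``tangents`` may be supplied analytically (phantoms) or are estimated by
    central differences. Curvature is computed on demand via
    :func:`curvature_profile`.
    """

    points: np.ndarray
    tangents: Optional[np.ndarray] = None
    proximal_tag: str = "proximal"
    distal_tag: str = "distal"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("centerline points must be (n, 3)")
        if len(self.points) < 2:
            raise ValueError("centerline needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("centerline arc length must be strictly increasing")
        self.arclength_mm = np.concatenate([[0.0], np.cumsum(seg)])
        if self.tangents is None:
            self.tangents = self._finite_difference_tangents()
        else:
            self.tangents = np.asarray(self.tangents, dtype=float)
            self.tangents /= np.linalg.norm(self.tangents, axis=1, keepdims=True)

    def _finite_difference_tangents(self) -> np.ndarray:
        p = self.points
        t = np.empty_like(p)
        t[1:-1] = p[2:] - p[:-2]
        t[0] = p[1] - p[0]
        t[-1] = p[-1] - p[-2]
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    @property
    def length_mm(self) -> float:
        return float(self.arclength_mm[-1])

    @property
    def endpoint_distance_mm(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    def at(self, s) -> tuple[np.ndarray, np.ndarray]:
        """Point and unit tangent at arc length(s) ``s`` (linear interpolation)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        pt = np.column_stack([np.interp(s, self.arclength_mm, self.points[:, k])
                              for k in range(3)])
        tg = np.column_stack([np.interp(s, self.arclength_mm, self.tangents[:, k])
                              for k in range(3)])
        tg /= np.linalg.norm(tg, axis=1, keepdims=True)
        if pt.shape[0] == 1:
            return pt[0], tg[0]
        return pt, tg

    def resampled(self, step_mm: float) -> "Centerline":
        n = max(2, int(round(self.length_mm / step_mm)) + 1)
        s = np.linspace(0.0, self.length_mm, n)
        pts, _ = self.at(s)
        return Centerline(pts, proximal_tag=self.proximal_tag, distal_tag=self.distal_tag)


def tortuosity(c: Centerline) -> float:
    """1 - d/l: d the straight distance between the endpoints, l the length
    along the centerline. 0 for a straight segment, approaching 1 for a coil."""
    l = c.length_mm
    if l <= 0:
        raise ValueError("degenerate centerline: zero arc length")
    return 1.0 - c.endpoint_distance_mm / l


def curvature_profile(c: Centerline,
                      smoothing_window_mm: float = DEFAULT_CURVATURE_WINDOW_MM
                      ) -> np.ndarray:
    """Per-point curvature (mm^-1) by Menger (circumscribed-circle) curvature
    of consecutive triples after moving-average smoothing of the polyline.

    Smoothing (default 5 mm window) suppresses mesh-faceting noise; endpoints
    copy the nearest interior value. Collinear triples give 0.
    """
    if len(c.points) < 3:
        raise ValueError("need at least 3 points for curvature")
    spacing = float(np.mean(np.diff(c.arclength_mm)))
    w = max(1, int(round(smoothing_window_mm / max(spacing, 1e-9))))
    if w % 2 == 0:
        w += 1
    p = uniform_filter1d(c.points, size=w, axis=0, mode="nearest") if w > 1 else c.points
    a, b, cc = p[:-2], p[1:-1], p[2:]
    ab = b - a
    bc = cc - b
    ca = a - cc
    cross = np.cross(ab, -ca)
    num = 2.0 * np.linalg.norm(cross, axis=1)
    den = (np.linalg.norm(ab, axis=1) * np.linalg.norm(bc, axis=1)
           * np.linalg.norm(ca, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.where(den > 1e-12, num / den, 0.0)
    n = len(c.points)
    out = np.empty(n)
    out[1:-1] = kappa
    # points whose smoothing window overlaps the padded ends are biased toward
    # the chord; copy the nearest cleanly-supported interior value instead
    hw = (w - 1) // 2
    lo = min(hw + 1, n // 2)
    hi = max(n - 2 - hw, n // 2)
    out[:lo + 1] = out[lo + 1] if lo + 1 < n else out[n // 2]
    out[hi:] = out[hi - 1] if hi >= 1 else out[n // 2]
    return out


# ---------------------------------------------------------------------------
# plane sections
# ---------------------------------------------------------------------------

def _section_contours(mesh: SurfaceMesh, origin, normal) -> list[np.ndarray]:
    """Closed intersection polylines of the mesh with a plane, as (k, 3)
    arrays (first point not repeated)."""
    sec = mesh.as_trimesh().section(plane_origin=origin, plane_normal=normal)
    if sec is None:
        return []
    out = []
    for poly in sec.discrete:
        p = np.asarray(poly, dtype=float)
        if len(p) >= 4 and np.allclose(p[0], p[-1]):
            p = p[:-1]
        if len(p) >= 3:
            out.append(p)
    return out


@dataclass
class CrossSection:
    """One perpendicular slice: plane, closed contour(s), per-slice metrics.

    The ``primary`` contour is the one enclosing the centerline point; other
    intersections at the same station (e.g. the FL when slicing a combined
    dissected surface) are kept with label ``secondary``. Metrics refer to the
    primary contour.
    """

    s_mm: float
    origin: np.ndarray
    normal: np.ndarray
    contours: list  # of (points3d, label)
    metrics: dict = field(default_factory=dict)

    @property
    def primary(self) -> np.ndarray:
        for pts, label in self.contours:
            if label == "primary":
                return pts
        raise ValueError(f"station {self.s_mm} mm has no primary contour")

    def primary_2d(self) -> np.ndarray:
        return to_plane_coords(self.primary, self.origin, self.normal)


def slice_sections(mesh: SurfaceMesh, c: Centerline,
                   interval_mm: float = DEFAULT_SLICE_INTERVAL_MM,
                   region: Optional[str] = None) -> list[CrossSection]:
    """Slice the mesh perpendicular to the centerline every ``interval_mm``.

    Stations run from the proximal end inclusive to the distal end inclusive;
    a final partial interval is dropped. Stations where the plane misses the
    region are dropped with a log entry. Contours not enclosing the centerline
    point are labeled ``secondary``.
    """
    n = int(np.floor(c.length_mm / interval_mm + 1e-9)) + 1
    eps = min(1e-3, 0.01 * c.length_mm)
    sections = []
    for i in range(n):
        s = i * interval_mm
        s_eff = float(np.clip(s, eps, c.length_mm - eps))
        origin, normal = c.at(s_eff)
        contours = _section_contours(mesh, origin, normal)
        if not contours:
            log.info("slice_sections: station %.3f mm (%s) has no intersection, dropped",
                     s, region or mesh.label or "mesh")
            continue
        labeled = []
        found_primary = False
        pt2 = to_plane_coords(origin[None, :], origin, normal)[0]
        polys2d = [to_plane_coords(p, origin, normal) for p in contours]
        for p3, p2 in zip(contours, polys2d):
            poly = Polygon(p2)
            if not found_primary and poly.is_valid and poly.contains(Point(pt2)):
                labeled.append((p3, "primary"))
                found_primary = True
            else:
                labeled.append((p3, "secondary"))
        if not found_primary:
            # centerline point just outside due to discretization: nearest centroid
            d = [np.linalg.norm(polygon_area_centroid_2d(p2)[1] - pt2) for p2 in polys2d]
            j = int(np.argmin(d))
            labeled[j] = (labeled[j][0], "primary")
        sections.append(CrossSection(s_mm=float(s), origin=origin, normal=normal,
                                     contours=labeled))
    return sections


def _max_feret(points2d: np.ndarray) -> tuple[float, np.ndarray]:
    """Maximum caliper (Feret) diameter of a planar point set and its unit
    direction; brute force over convex-hull vertex pairs."""
    from scipy.spatial import ConvexHull
    if len(points2d) > 3:
        try:
            hull = points2d[ConvexHull(points2d).vertices]
        except Exception:  # nearly-degenerate contour
            hull = points2d
    else:
        hull = points2d
    diff = hull[:, None, :] - hull[None, :, :]
    d2 = (diff ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    direction = hull[i] - hull[j]
    nd = np.linalg.norm(direction)
    return float(nd), (direction / nd if nd > 0 else np.array([1.0, 0.0]))


def section_metrics(cs: CrossSection) -> CrossSection:
    """Fill per-slice metrics of the primary contour.

    area: planar shoelace; circumference: polygon perimeter;
    equivalent_diameter: 2*sqrt(area/pi); transverse_diameter: maximum Feret
    (caliper) diameter; longitudinal_diameter: extent perpendicular to the
    transverse direction; aspect_ratio: transverse/longitudinal (>= 1).
    """
    p2 = cs.primary_2d()
    poly = Polygon(p2)
    if not poly.is_valid or not poly.is_simple:
        raise ValueError(f"self-intersecting contour at station {cs.s_mm} mm")
    area, _ = polygon_area_centroid_2d(p2)
    closed = np.vstack([p2, p2[:1]])
    circumference = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
    transverse, direction = _max_feret(p2)
    perp = np.array([-direction[1], direction[0]])
    proj = p2 @ perp
    longitudinal = float(proj.max() - proj.min())
    cs.metrics = {
        "area_mm2": float(area),
        "circumference_mm": circumference,
        "equivalent_diameter_mm": 2.0 * np.sqrt(area / np.pi),
        "transverse_diameter_mm": transverse,
        "longitudinal_diameter_mm": longitudinal,
        "aspect_ratio": transverse / longitudinal if longitudinal > 0 else np.inf,
    }
    return cs


def lumen_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume (mm^3) by the divergence theorem over triangles."""
    tm = mesh.as_trimesh()
    if not tm.is_watertight:
        raise MeshIntegrityError("volume requires a watertight mesh")
    v = float(tm.volume)
    if v < 0:
        warnings.warn("mesh was inward-oriented; orientation auto-fixed for volume")
        v = -v
    return v


def oversizing(stent_proximal_diam_mm: float, stent_distal_diam_mm: float,
               vessel_proximal_diam_mm: float, vessel_distal_diam_mm: float
               ) -> tuple[float, float]:
    """Stent-graft diameter oversizing, percent of the local vessel diameter:
    100*(D_stent - D_vessel)/D_vessel at the proximal and distal landing zones."""
    d = (stent_proximal_diam_mm, stent_distal_diam_mm,
         vessel_proximal_diam_mm, vessel_distal_diam_mm)
    if any(x <= 0 for x in d):
        raise ValueError("all diameters must be positive")
    prox = 100.0 * (stent_proximal_diam_mm - vessel_proximal_diam_mm) / vessel_proximal_diam_mm
    dist = 100.0 * (stent_distal_diam_mm - vessel_distal_diam_mm) / vessel_distal_diam_mm
    return prox, dist


# ---------------------------------------------------------------------------
# centerline extraction
# ---------------------------------------------------------------------------

_PARITY_DIR = np.array([0.577215, 0.707107, 0.414214])
_PARITY_DIR = _PARITY_DIR / np.linalg.norm(_PARITY_DIR)


def _inside(tq: TriangleQuery, point: np.ndarray, diameter: float) -> bool:
    t, _, _ = tq._ray_hits(np.asarray(point, dtype=float), _PARITY_DIR,
                           np.arange(len(tq.tri)))
    return (t > 1e-9).sum() % 2 == 1


def _recenter(mesh: SurfaceMesh, point: np.ndarray, tangent: np.ndarray,
              prefer_near: Optional[float] = None):
    """Area centroid of the section contour through ``point`` perpendicular to
    ``tangent``. Returns (centroid3d, area) or None when the plane misses."""
    contours = _section_contours(mesh, point, tangent)
    if not contours:
        return None
    pt2 = np.zeros(2)
    best = None
    cands = []
    for p3 in contours:
        p2 = to_plane_coords(p3, point, tangent)
        area, cen2 = polygon_area_centroid_2d(p2)
        dist = np.linalg.norm(cen2 - pt2)
        contains = Polygon(p2).contains(Point(pt2)) if Polygon(p2).is_valid else False
        cands.append((contains, dist, area, cen2))
    containing = [c for c in cands if c[0]]
    pool = containing if containing else cands
    pool = sorted(pool, key=lambda c: c[1])
    if len(pool) >= 2 and not containing:
        d0, d1 = pool[0][1], pool[1][1]
        a0, a1 = pool[0][2], pool[1][2]
        if d1 > 0 and d0 / d1 > 0.9 and min(a0, a1) / max(a0, a1) > 0.5:
            raise BranchAmbiguityError(
                "two comparable lumen continuations near "
                f"{np.round(point, 2)}; add an intermediate seed")
    _, _, area, cen2 = pool[0]
    u, v = plane_basis(tangent)
    return point + cen2[0] * u + cen2[1] * v, area


def _local_axis(mesh: SurfaceMesh, tq: TriangleQuery, seed: np.ndarray,
                toward: np.ndarray) -> np.ndarray:
    """Initial marching direction: principal axis of the surface patch around
    the seed, oriented toward the other seed."""
    _, d, _, _ = tq.closest_point(seed[None, :])
    r_est = max(float(d[0]), 1.0)
    mask = np.linalg.norm(mesh.vertices - seed, axis=1) < 3.0 * r_est
    patch = mesh.vertices[mask] if mask.sum() >= 8 else mesh.vertices
    cov = np.cov((patch - patch.mean(axis=0)).T)
    _, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    if axis @ toward < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _initial_tangent(mesh: SurfaceMesh, tq: TriangleQuery, seed: np.ndarray,
                     other: np.ndarray, step_mm: float = 1.0):
    """Best starting direction at a seed.

    Among the seed-to-seed chord, the local patch axis and the three global
    principal axes, pick the direction whose perpendicular section through
    the seed has the smallest area — the true tube tangent minimizes the cut.
    The sign is then chosen by a trial step: the direction must keep the
    march inside the lumen and, when both signs do, advance toward the other
    seed."""
    chord = other - seed
    chord = chord / np.linalg.norm(chord)
    cands = [chord, _local_axis(mesh, tq, seed, chord)]
    cov = np.cov((mesh.vertices - mesh.vertices.mean(axis=0)).T)
    _, evecs = np.linalg.eigh(cov)
    cands += [evecs[:, k] for k in range(3)]
    best_t, best_rc, best_area = cands[0], None, np.inf
    for t in cands:
        try:
            rc = _recenter(mesh, seed, t)
        except BranchAmbiguityError:
            rc = None
        if rc is not None and rc[1] < best_area:
            best_t, best_rc, best_area = t, rc, rc[1]
    if best_rc is None:
        return best_t, None
    p0 = best_rc[0]
    scores = {}
    for sign in (1.0, -1.0):
        t = sign * best_t
        try:
            rc = _recenter(mesh, p0 + step_mm * t, t)
        except BranchAmbiguityError:
            rc = None
        if rc is not None:
            scores[sign] = (rc[0] - p0) @ (other - p0)
    if not scores:
        return best_t, best_rc
    sign = max(scores, key=scores.get)
    return sign * best_t, best_rc


def extract_centerline(mesh: SurfaceMesh, seed_proximal, seed_distal,
                       step_mm: float = 1.0, max_steps: int = 5000) -> Centerline:
    """Seeded centroid-marching centerline from the proximal to the distal seed.

    March along the local tangent, re-centering each step at the area centroid
    of the perpendicular cross-section; two fixed-point refinement passes with
    central-difference tangents; final resampling at ``step_mm``. Deterministic
    and mesh-only (no voxelization). Seeds must lie inside the lumen.
    """
    seed_p = np.asarray(seed_proximal, dtype=float)
    seed_d = np.asarray(seed_distal, dtype=float)
    tq = TriangleQuery(mesh.vertices, mesh.faces)
    diam = float(np.linalg.norm(mesh.vertices.max(0) - mesh.vertices.min(0)))
    for name, s in (("proximal", seed_p), ("distal", seed_d)):
        if not _inside(tq, s, diam):
            raise ValueError(f"{name} seed {np.round(s, 2)} lies outside the lumen")

    t0, rc = _initial_tangent(mesh, tq, seed_p, seed_d)
    if rc is None:
        raise ValueError("cannot section the lumen at the proximal seed")
    points = [rc[0]]
    _, rc_d = _initial_tangent(mesh, tq, seed_d, seed_p)
    distal_pt = rc_d[0] if rc_d is not None else seed_d

    tangent = t0
    for _ in range(max_steps):
        p = points[-1]
        if np.linalg.norm(distal_pt - p) <= step_mm:
            break
        guess = p + step_mm * tangent
        rc = _recenter(mesh, guess, tangent)
        if rc is None:
            break
        p_new = rc[0]
        step_vec = p_new - p
        nrm = np.linalg.norm(step_vec)
        if nrm < 1e-9:
            break
        new_tan = step_vec / nrm
        # keep marching direction stable: blend with previous tangent
        tangent = 0.5 * tangent + 0.5 * new_tan
        tangent /= np.linalg.norm(tangent)
        points.append(p_new)
        # overshoot guard: heading away from distal and close to it
        if (distal_pt - p_new) @ tangent < 0 and np.linalg.norm(distal_pt - p_new) < 2 * step_mm:
            break
    if np.linalg.norm(distal_pt - points[-1]) > 1e-9:
        points.append(distal_pt)
    pts = np.asarray(points)

    # fixed-point refinement: recenter interior points on planes normal to the
    # central-difference tangents. Endpoints stay anchored (their slightly
    # tilted planes can cut into an end cap) and moves larger than one step
    # are rejected as cap/branch artifacts.
    for _ in range(2):
        cl = Centerline(_dedupe(pts))
        new_pts = cl.points.copy()
        for i in range(1, len(cl.points) - 1):
            rc = _recenter(mesh, cl.points[i], cl.tangents[i])
            if rc is not None and np.linalg.norm(rc[0] - cl.points[i]) <= step_mm:
                new_pts[i] = rc[0]
        pts = new_pts
    return Centerline(_dedupe(pts)).resampled(step_mm)


def _dedupe(points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    keep = [0]
    for i in range(1, len(points)):
        if np.linalg.norm(points[i] - points[keep[-1]]) > tol:
            keep.append(i)
    return points[keep]


# ---------------------------------------------------------------------------
# morphometry table
# ---------------------------------------------------------------------------

@dataclass
class MorphometryTable:
    """Per-station slice metrics for a named region plus region scalars
    (volume, tortuosity, mean/max curvature)."""

    region: str
    stations: pd.DataFrame
    scalars: dict

    def to_csv(self, path) -> None:
        self.stations.to_csv(path, index=False, float_format="%.10g")

    def to_json(self, path) -> None:
        import json
        Path(path).write_text(json.dumps(self.scalars, indent=1, sort_keys=True))


def morphometry_table(mesh: SurfaceMesh, c: Centerline,
                      interval_mm: float = DEFAULT_SLICE_INTERVAL_MM,
                      region: Optional[str] = None,
                      curvature_window_mm: float = DEFAULT_CURVATURE_WINDOW_MM
                      ) -> MorphometryTable:
    """Full morphometric summary of one region: per-station slice metrics and
    whole-region scalars."""
    region = region or mesh.label or "region"
    sections = [section_metrics(cs) for cs in slice_sections(mesh, c, interval_mm, region)]
    rows = [{"s_mm": cs.s_mm, **cs.metrics} for cs in sections]
    df = pd.DataFrame(rows)
    kappa = curvature_profile(c, curvature_window_mm)
    scalars = {
        "region": region,
        "volume_mm3": lumen_volume(mesh) if mesh.is_watertight else None,
        "tortuosity": tortuosity(c),
        "mean_curvature_per_mm": float(np.mean(kappa)),
        "max_curvature_per_mm": float(np.max(kappa)),
        "centerline_length_mm": c.length_mm,
        "n_stations": len(df),
    }
    return MorphometryTable(region=region, stations=df, scalars=scalars)
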