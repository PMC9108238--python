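"""Synthetic vessel phantoms with analytically known ground truth.

Stand-ins for patient CTA reconstructions and CFD output: parametric tubes
(straight, torus segment, composite arch), a two-lumen dissected segment with
a flat septum, prescribed pressure/WSS fields with closed-form time integrals,
and controlled deformations (rigid motion + radial growth) between synthetic
"timepoints". Every phantom carries its exact centerline, so morphometric and
hemodynamic code can be validated against closed forms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .mesh_io import FieldTimeSeries, SurfaceMesh, write_field_table, write_surface
from .centerline_morph import Centerline
from .registration import RigidTransform

TUBE_KINDS = ("straight_tube", "torus_segment", "composite_arch")

#: circumferential vertex count per ring (default); axial rings at ~1/mm
DEFAULT_MESH_DENSITY = 64

#: cardiac periods mirroring 55 (pre) and 85 (post) beats/min
PERIOD_PRE_S = 60.0 / 55.0
PERIOD_POST_S = 60.0 / 85.0


@dataclass
class PhantomSpec:
    """Parameters of a synthetic vessel phantom (lengths in mm)."""

    kind: str
    radius_mm: float
    length_mm: float = 100.0
    arc_angle_deg: float = 180.0
    bend_radius_mm: float = 50.0
    septum_fraction: float = 0.5
    tear_arclengths_mm: list = dc_field(default_factory=list)
    mesh_density: int = DEFAULT_MESH_DENSITY
    seed: int = 0

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.mesh_density < 8:
            raise ValueError("mesh_density must be >= 8")
        if self.kind in ("torus_segment", "composite_arch"):
            if self.bend_radius_mm <= 0 or self.radius_mm >= self.bend_radius_mm:
                raise ValueError("need 0 < radius_mm < bend_radius_mm for curved kinds")
            if self.arc_angle_deg <= 0:
                raise ValueError("arc_angle_deg must be positive")
        if self.kind in ("straight_tube", "dissected_segment", "composite_arch"):
            if self.length_mm <= 0:
                raise ValueError("length_mm must be positive")
        if self.kind == "dissected_segment":
            if not (0.0 < self.septum_fraction < 1.0):
                raise ValueError("septum_fraction must be in (0, 1)")


@dataclass
class FieldSpec:
    """A prescribed surface field: spatial form plus cosine pulsatility.

    ``pulsatile_cosine`` produces value(t) = base + amplitude*cos(2*pi*t/T +
    phase) so all cycle integrals are closed-form. 50 timesteps per cycle is
    the default temporal resolution.
    """

    form: str  # uniform | axial_linear | pulsatile_cosine
    base_value: float = 0.0
    axial_slope: float = 0.0  # units per mm, for axial_linear
    amplitude: float = 0.0
    period_s: float = 1.0
    phase_rad: float = 0.0
    n_timesteps: int = 50
    units: str = ""

    def __post_init__(self):
        if self.form not in ("uniform", "axial_linear", "pulsatile_cosine"):
            raise ValueError(f"unknown field form {self.form!r}")
        if self.n_timesteps < 2:
            raise ValueError("n_timesteps must be >= 2")
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")


# ---------------------------------------------------------------------------
# parametric tube construction
# ---------------------------------------------------------------------------

def _centerline_frames(spec: PhantomSpec, max_ring_spacing_mm: float = 1.0):
    """Sample the analytic axis: points, tangents and an orthonormal frame
    (n1, n2) with n1 x n2 = tangent, at <= max_ring_spacing_mm arc spacing."""
    if spec.kind == "straight_tube" or spec.kind == "dissected_segment":
        L = spec.length_mm
        n = max(2, int(np.ceil(L / max_ring_spacing_mm)) + 1)
        s = np.linspace(0.0, L, n)
        pts = np.column_stack([np.zeros(n), np.zeros(n), s])
        tan = np.tile([0.0, 0.0, 1.0], (n, 1))
        n1 = np.tile([1.0, 0.0, 0.0], (n, 1))
        n2 = np.tile([0.0, 1.0, 0.0], (n, 1))
        return s, pts, tan, n1, n2
    if spec.kind == "torus_segment":
        R = spec.bend_radius_mm
        theta_max = np.deg2rad(spec.arc_angle_deg)
        L = R * theta_max
        n = max(2, int(np.ceil(L / max_ring_spacing_mm)) + 1)
        theta = np.linspace(0.0, theta_max, n)
        s = R * theta
        pts = np.column_stack([R * np.cos(theta), R * np.sin(theta), np.zeros(n)])
        tan = np.column_stack([-np.sin(theta), np.cos(theta), np.zeros(n)])
        n1 = np.tile([0.0, 0.0, 1.0], (n, 1))
        n2 = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n)])
        return s, pts, tan, n1, n2
    if spec.kind == "composite_arch":
        # inlet straight (length_mm, along +z), arc bending toward +x in the
        # x-z plane, outlet straight (0.6*length_mm). Unequal straights break
        # the 180-degree symmetry so rigid registration is identifiable.
        L1 = spec.length_mm
        L2 = 0.6 * spec.length_mm
        R = spec.bend_radius_mm
        A = np.deg2rad(spec.arc_angle_deg)
        segs = []
        # straight 1
        n1s = max(2, int(np.ceil(L1 / max_ring_spacing_mm)) + 1)
        t1 = np.linspace(0.0, L1, n1s)
        seg1_pts = np.column_stack([np.zeros(n1s), np.zeros(n1s), t1])
        seg1_tan = np.tile([0.0, 0.0, 1.0], (n1s, 1))
        segs.append((t1, seg1_pts, seg1_tan))
        # arc: center (R, 0, L1)
        arc_len = R * A
        n2s = max(2, int(np.ceil(arc_len / max_ring_spacing_mm)) + 1)
        alpha = np.linspace(0.0, A, n2s)
        arc_pts = np.column_stack([R - R * np.cos(alpha), np.zeros(n2s), L1 + R * np.sin(alpha)])
        arc_tan = np.column_stack([np.sin(alpha), np.zeros(n2s), np.cos(alpha)])
        segs.append((L1 + R * alpha, arc_pts, arc_tan))
        # straight 2
        n3s = max(2, int(np.ceil(L2 / max_ring_spacing_mm)) + 1)
        t3 = np.linspace(0.0, L2, n3s)
        end0 = arc_pts[-1]
        tanA = arc_tan[-1]
        seg3_pts = end0[None, :] + t3[:, None] * tanA[None, :]
        seg3_tan = np.tile(tanA, (n3s, 1))
        segs.append((L1 + arc_len + t3, seg3_pts, seg3_tan))
        s = np.concatenate([segs[0][0], segs[1][0][1:], segs[2][0][1:]])
        pts = np.vstack([segs[0][1], segs[1][1][1:], segs[2][1][1:]])
        tan = np.vstack([segs[0][2], segs[1][2][1:], segs[2][2][1:]])
        ny = np.tile([0.0, 1.0, 0.0], (len(s), 1))
        n1 = np.cross(ny, tan)
        return s, pts, tan, n1, ny
    raise ValueError(f"unknown phantom kind {spec.kind!r}")


def _loft_tube(ring_points_2d: np.ndarray, pts, tan, n1, n2,
               normals_2d: Optional[np.ndarray] = None):
    """Extrude a fixed CCW cross-section polygon along a framed centerline and
    cap both ends with fans from the polygon centroid.

    ``ring_points_2d``: (k, 2) polygon in the (n1, n2) plane, CCW when viewed
    against the tangent. Returns (vertices, faces, vertex_normals).
    """
    k = len(ring_points_2d)
    n_rings = len(pts)
    ring = ring_points_2d
    verts = (pts[:, None, :]
             + ring[None, :, 0:1] * n1[:, None, :]
             + ring[None, :, 1:2] * n2[:, None, :]).reshape(n_rings * k, 3)
    if normals_2d is None:
        # radial: normalize the 2D offset
        nrm2 = ring / np.linalg.norm(ring, axis=1, keepdims=True)
    else:
        nrm2 = normals_2d
    vnorm = (nrm2[None, :, 0:1] * n1[:, None, :]
             + nrm2[None, :, 1:2] * n2[:, None, :]).reshape(n_rings * k, 3)

    faces = []
    for j in range(n_rings - 1):
        base0 = j * k
        base1 = (j + 1) * k
        for i in range(k):
            i2 = (i + 1) % k
            faces.append((base0 + i, base0 + i2, base1 + i2))
            faces.append((base0 + i, base1 + i2, base1 + i))
    # caps
    from ._geometry import polygon_area_centroid_2d
    _, cen2 = polygon_area_centroid_2d(ring)
    cen_prox = pts[0] + cen2[0] * n1[0] + cen2[1] * n2[0]
    cen_dist = pts[-1] + cen2[0] * n1[-1] + cen2[1] * n2[-1]
    ip = n_rings * k
    idist = ip + 1
    verts = np.vstack([verts, cen_prox[None, :], cen_dist[None, :]])
    vnorm = np.vstack([vnorm, -tan[0][None, :], tan[-1][None, :]])
    for i in range(k):
        i2 = (i + 1) % k
        faces.append((ip, i2, i))                               # proximal, -t
        base = (n_rings - 1) * k
        faces.append((idist, base + i, base + i2))              # distal, +t
    return verts, np.asarray(faces, dtype=np.int64), vnorm


def make_tube(spec: PhantomSpec) -> tuple[SurfaceMesh, Centerline]:
    """Watertight tubular phantom plus its exact analytic centerline
    (sampled at <= 0.5 mm spacing)."""
    if spec.kind not in TUBE_KINDS:
        raise ValueError(f"make_tube requires a tubular kind, got {spec.kind!r}")
    s, pts, tan, n1, n2 = _centerline_frames(spec)
    phi = 2.0 * np.pi * np.arange(spec.mesh_density) / spec.mesh_density
    ring = spec.radius_mm * np.column_stack([np.cos(phi), np.sin(phi)])
    verts, faces, vnorm = _loft_tube(ring, pts, tan, n1, n2)
    mesh = SurfaceMesh(verts, faces, label=spec.kind, vertex_normals=vnorm,
                       metadata={
                           "phantom": spec.kind,
                           "radius_mm": spec.radius_mm,
                           "axis_origin": [0.0, 0.0, 0.0],
                           "axis_direction": [0.0, 0.0, 1.0],
                       })
    if mesh.as_trimesh().volume <= 0:  # pragma: no cover - construction guard
        raise AssertionError("phantom mesh is not outward-oriented")
    sc, pc, tc, _, _ = _centerline_frames(spec, max_ring_spacing_mm=0.5)
    cl = Centerline(points=pc, tangents=tc)
    return mesh, cl


# ---------------------------------------------------------------------------
# dissected two-lumen phantom
# ---------------------------------------------------------------------------

def _septum_offset(radius: float, area_fraction: float) -> float:
    """Chord offset h such that the circular segment {x >= h} of a disk of the
    given radius has the requested area fraction."""
    target = area_fraction * np.pi * radius ** 2

    def seg_area(h):
        return radius ** 2 * np.arccos(h / radius) - h * np.sqrt(radius ** 2 - h ** 2)

    return brentq(lambda h: seg_area(h) - target, -radius * (1 - 1e-12),
                  radius * (1 - 1e-12), xtol=1e-12)


def _segment_polygons(radius: float, h: float, n_circ: int):
    """CCW polygons (and outward 2D normals) for the two circular segments cut
    by the chord x = h: the TL {x >= h} and the FL {x <= h}."""
    phi0 = np.arccos(np.clip(h / radius, -1.0, 1.0))
    y0 = radius * np.sin(phi0)
    spacing = 2.0 * np.pi * radius / n_circ

    def arc(a, b):
        n = max(3, int(np.ceil(abs(b - a) * radius / spacing)) + 1)
        ph = np.linspace(a, b, n)
        p = radius * np.column_stack([np.cos(ph), np.sin(ph)])
        nrm = np.column_stack([np.cos(ph), np.sin(ph)])
        return p, nrm

    def chord(y_from, y_to, outward_x):
        n = max(2, int(np.ceil(abs(y_to - y_from) / spacing)) + 1)
        ys = np.linspace(y_from, y_to, n)[1:-1]  # endpoints belong to the arc
        p = np.column_stack([np.full(len(ys), h), ys])
        nrm = np.tile([outward_x, 0.0], (len(ys), 1))
        return p, nrm

    tl_arc, tl_arc_n = arc(-phi0, phi0)
    tl_ch, tl_ch_n = chord(y0, -y0, -1.0)
    tl_poly = np.vstack([tl_arc, tl_ch])
    tl_nrm = np.vstack([tl_arc_n, tl_ch_n])

    fl_arc, fl_arc_n = arc(phi0, 2.0 * np.pi - phi0)
    fl_ch, fl_ch_n = chord(-y0, y0, 1.0)
    fl_poly = np.vstack([fl_arc, fl_ch])
    fl_nrm = np.vstack([fl_arc_n, fl_ch_n])
    return (tl_poly, tl_nrm), (fl_poly, fl_nrm)


def make_dissected_phantom(spec: PhantomSpec):
    """Two watertight lumens (TL, FL) separated by a flat chord septum along a
    straight dissected segment, plus the shared axis centerline and tear
    annotations (arc-length positions, sorted ascending).

    The TL cross-sectional area fraction equals ``septum_fraction`` by
    construction (circular-segment closed form).
    """
    if spec.kind != "dissected_segment":
        raise ValueError("make_dissected_phantom requires kind='dissected_segment'")
    for t in spec.tear_arclengths_mm:
        if not (0.0 <= t <= spec.length_mm):
            raise ValueError(f"tear arc-length {t} mm outside segment [0, {spec.length_mm}]")
    h = _septum_offset(spec.radius_mm, spec.septum_fraction)
    (tl_poly, tl_nrm), (fl_poly, fl_nrm) = _segment_polygons(
        spec.radius_mm, h, spec.mesh_density)
    s, pts, tan, n1, n2 = _centerline_frames(spec)
    meshes = []
    for label, poly, nrm in (("TL", tl_poly, tl_nrm), ("FL", fl_poly, fl_nrm)):
        v, f, vn = _loft_tube(poly, pts, tan, n1, n2, normals_2d=nrm)
        meshes.append(SurfaceMesh(v, f, label=label, vertex_normals=vn,
                                  metadata={
                                      "phantom": "dissected_segment",
                                      "radius_mm": spec.radius_mm,
                                      "septum_fraction": spec.septum_fraction,
                                      "septum_offset_mm": h,
                                      "axis_origin": [0.0, 0.0, 0.0],
                                      "axis_direction": [0.0, 0.0, 1.0],
                                  }))
    sc, pc, tc, _, _ = _centerline_frames(spec, max_ring_spacing_mm=0.5)
    cl = Centerline(points=pc, tangents=tc)
    tears = [{"s_mm": float(t)} for t in sorted(spec.tear_arclengths_mm)]
    return meshes[0], meshes[1], cl, tears


# ---------------------------------------------------------------------------
# prescribed fields
# ---------------------------------------------------------------------------

def make_field_series(mesh: SurfaceMesh, spec: FieldSpec, kind: str = "scalar",
                      direction=None, name: str = "field") -> FieldTimeSeries:
    """Prescribe a per-vertex field on a phantom surface.

    Spatial forms: ``uniform`` (base everywhere), ``axial_linear``
    (base + slope * s with s the projection onto the phantom axis, mm).
    ``pulsatile_cosine`` modulates a uniform base in time. Vector fields point
    along ``direction`` (default: the phantom axis) with the scalar form as
    magnitude; negative values reverse the direction, which is what makes a
    zero-mean cosine a fully reversing WSS.
    """
    nt = spec.n_timesteps
    times = np.arange(nt) * spec.period_s / nt
    nv = mesh.n_vertices
    origin = np.asarray(mesh.metadata.get("axis_origin", [0.0, 0.0, 0.0]))
    axis = np.asarray(mesh.metadata.get("axis_direction", [0.0, 0.0, 1.0]), dtype=float)
    axis = axis / np.linalg.norm(axis)

    if spec.form == "uniform":
        spatial = np.full(nv, spec.base_value)
        temporal = np.ones(nt)
    elif spec.form == "axial_linear":
        s_coord = (mesh.vertices - origin) @ axis
        spatial = spec.base_value + spec.axial_slope * s_coord
        temporal = np.ones(nt)
    else:  # pulsatile_cosine
        spatial = np.ones(nv)
        temporal = (spec.base_value
                    + spec.amplitude * np.cos(2.0 * np.pi * times / spec.period_s
                                              + spec.phase_rad))
    values = temporal[:, None] * spatial[None, :]
    if kind == "vector3":
        d = axis if direction is None else np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        values = values[:, :, None] * d[None, None, :]
    elif kind != "scalar":
        raise ValueError(f"unknown series kind {kind!r}")
    return FieldTimeSeries(name, kind, values, times, spec.period_s, spec.units)


# ---------------------------------------------------------------------------
# deformation ground truth
# ---------------------------------------------------------------------------

def deform_phantom(mesh: SurfaceMesh, transform: RigidTransform,
                   radial_growth_mm: float = 0.0) -> SurfaceMesh:
    """Grow the surface along its outward (analytic, if available) normals and
    then apply a rigid transform. The ground truth is recorded in metadata.
    """
    r = mesh.metadata.get("radius_mm")
    if r is not None and radial_growth_mm <= -r:
        raise ValueError(f"growth {radial_growth_mm} mm would collapse the lumen (r={r} mm)")
    normals = mesh.outward_normals()
    grown = mesh.vertices + radial_growth_mm * normals
    moved = grown @ transform.rotation.T + transform.translation
    out = mesh.copy(vertices=moved,
                    vertex_normals=normals @ transform.rotation.T)
    if "axis_origin" in out.metadata:
        out.metadata["axis_origin"] = transform.apply(
            np.asarray(out.metadata["axis_origin"])[None, :])[0].tolist()
        out.metadata["axis_direction"] = (
            np.asarray(out.metadata["axis_direction"]) @ transform.rotation.T).tolist()
    out.metadata["true_transform"] = transform.to_dict()
    out.metadata["true_growth_mm"] = float(radial_growth_mm)
    if r is not None:
        out.metadata["radius_mm"] = r + radial_growth_mm
    return out


def write_phantom_bundle(out_dir, name: str, mesh: SurfaceMesh,
                         centerline: Centerline,
                         fields: Optional[dict] = None,
                         ground_truth: Optional[dict] = None) -> None:
    """Persist a phantom: binary STL + ground-truth JSON sidecar + field CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_surface(mesh, out_dir / f"{name}.stl")
    gt = dict(ground_truth or {})
    gt.setdefault("centerline_points_mm", np.asarray(centerline.points).tolist())
    gt.update({k: v for k, v in mesh.metadata.items()
               if isinstance(v, (int, float, str, list))})
    (out_dir / f"{name}.groundtruth.json").write_text(
        json.dumps(gt, indent=1, sort_keys=True))
    for fname, series in (fields or {}).items():
        write_field_table(series, out_dir / f"{name}.{fname}.csv")
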