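"""Registered longitudinal comparison between two timepoints.

Surface correspondence by outward-normal ray casting, the normal deformation
index (signed wall displacement, expansion positive), per-vertex parameter
difference fields ΔX between timepoints, and the positive/negative area
ratios AR_P / AR_N that summarize whether a parameter rose or fell over the
follow-up interval.

Sign conventions. With reference timepoint A (earlier, e.g. Post-1) and
follow-up B (e.g. Post-2) two conventions for ΔX are supported:

* ``as_printed``:   ΔX = X_A - X_B (difference written earlier-minus-later);
  a parameter that decreased over time gives positive ΔX, so "decreased"
  shows up as dominant AR_P.
* ``as_described`` (default): ΔX = X_B - X_A; a decrease gives negative ΔX
  and dominant AR_N, matching the usual clinical reading that dominant AR_N
  means the parameter decreased from A to B.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._geometry import TriangleQuery
from .mesh_io import SurfaceMesh
from .registration import RigidTransform

log = logging.getLogger("aortamorph")

DEFAULT_RAY_CUTOFF_MM = 10.0
SIGN_CONVENTIONS = ("as_printed", "as_described")


@dataclass
class SurfaceCorrespondence:
    """For each vertex of reference surface A: the matched point on B.

    ``signed_distance_mm`` is along A's outward normal, positive when B lies
    outside A. ``fallback`` flags vertices matched by closest point (no normal
    ray hit within the cutoff) rather than ray casting.
    """

    a: SurfaceMesh
    b: SurfaceMesh
    signed_distance_mm: np.ndarray
    face_b: np.ndarray
    barycentric: np.ndarray
    fallback: np.ndarray
    poor_alignment: bool = False

    @property
    def matched_points(self) -> np.ndarray:
        tri = self.b.vertices[self.b.faces[self.face_b]]
        return np.einsum("ij,ijk->ik", self.barycentric, tri)

    def sample_b(self, values_b: np.ndarray) -> np.ndarray:
        """Barycentric interpolation of a per-vertex field on B at the
        matched points."""
        values_b = np.asarray(values_b, dtype=float)
        if len(values_b) != self.b.n_vertices:
            raise ValueError("field does not match B vertex count")
        vals = values_b[self.b.faces[self.face_b]]
        return np.einsum("ij,ij->i", self.barycentric, vals)


def correspond(a: SurfaceMesh, b: SurfaceMesh,
               t: Optional[RigidTransform] = None,
               cutoff_mm: float = DEFAULT_RAY_CUTOFF_MM) -> SurfaceCorrespondence:
    """Match every vertex of A to surface B (B mapped into A's frame by ``t``).

    Rays are cast from each A-vertex along ± its outward normal; the nearest
    intersection with B within ``cutoff_mm`` gives the signed normal distance.
    Vertices without a hit fall back to the closest point on B (signed by the
    normal). More than 20% fallback matches flags poor alignment.
    """
    if t is not None:
        from .registration import apply_transform
        b = apply_transform(b, t)
    tq = TriangleQuery(b.vertices, b.faces)
    normals = a.outward_normals()
    d, fid, bary, fallback = tq.signed_normal_distance(a.vertices, normals, cutoff_mm)
    frac = float(fallback.mean())
    poor = frac > 0.20
    if poor:
        warnings.warn(f"correspondence: {frac:.0%} fallback matches; alignment may be poor")
    return SurfaceCorrespondence(a=a, b=b, signed_distance_mm=d, face_b=fid,
                                 barycentric=bary, fallback=fallback,
                                 poor_alignment=poor)


@dataclass
class DeformationSummary:
    area_weighted_mean_mm: float
    min_mm: float
    max_mm: float
    fraction_positive: float


def normal_deformation_index(corr: SurfaceCorrespondence
                             ) -> tuple[np.ndarray, DeformationSummary]:
    """Signed wall displacement along the outward normal (mm), positive for
    luminal expansion from the reference to the follow-up surface.

    The summary mean and positive fraction are weighted by the vertex area
    share (one third of each incident triangle) on the reference surface.
    """
    index = corr.signed_distance_mm
    w = _vertex_areas(corr.a)
    mean = float(np.sum(index * w) / np.sum(w))
    frac_pos = float(np.sum(w[index > 0]) / np.sum(w))
    summary = DeformationSummary(area_weighted_mean_mm=mean,
                                 min_mm=float(index.min()),
                                 max_mm=float(index.max()),
                                 fraction_positive=frac_pos)
    return index, summary


def _vertex_areas(mesh: SurfaceMesh) -> np.ndarray:
    tri = mesh.vertices[mesh.faces]
    t_area = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    w = np.zeros(mesh.n_vertices)
    np.add.at(w, mesh.faces.ravel(), np.repeat(t_area / 3.0, 3))
    return w


@dataclass
class EvolutionField:
    """Per-vertex difference ΔX of one parameter between two registered
    timepoints, with area-weighted positive/negative area ratios."""

    parameter: str
    delta: np.ndarray
    triangle_areas_mm2: np.ndarray
    faces: np.ndarray
    sign_convention: str
    ar_p: float = np.nan
    ar_n: float = np.nan


def delta_field(x_a: np.ndarray, x_b: np.ndarray, corr: SurfaceCorrespondence,
                parameter: str = "X",
                sign_convention: str = "as_described") -> EvolutionField:
    """ΔX per reference vertex, sampling X_B at the matched points on B by
    barycentric interpolation. Fallback-quality matches give NaN and are
    excluded from the area ratios."""
    if sign_convention not in SIGN_CONVENTIONS:
        raise ValueError(f"sign_convention must be one of {SIGN_CONVENTIONS}")
    x_a = np.asarray(x_a, dtype=float)
    if len(x_a) != corr.a.n_vertices:
        raise ValueError("x_a does not match reference vertex count")
    x_b_matched = corr.sample_b(x_b)
    delta = x_a - x_b_matched if sign_convention == "as_printed" else x_b_matched - x_a
    delta = delta.copy()
    delta[corr.fallback] = np.nan
    tri = corr.a.vertices[corr.a.faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    ef = EvolutionField(parameter=parameter, delta=delta,
                        triangle_areas_mm2=areas, faces=corr.a.faces,
                        sign_convention=sign_convention)
    ef.ar_p, ef.ar_n = area_ratios(ef)
    return ef


def area_ratios(e: EvolutionField) -> tuple[float, float]:
    """AR_P and AR_N: fractions of reference surface area whose triangle-mean
    ΔX is positive / negative. Zero-mean triangles are counted in AR_P so
    AR_P + AR_N = 1 exactly; NaN triangles are excluded from the total."""
    tri_vals = e.delta[e.faces]
    tri_mean = tri_vals.mean(axis=1)
    valid = np.isfinite(tri_mean)
    if not np.any(valid):
        raise ValueError("all-NaN difference field")
    areas = e.triangle_areas_mm2[valid]
    total = areas.sum()
    pos = areas[tri_mean[valid] >= 0].sum()
    return float(pos / total), float((total - pos) / total)
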