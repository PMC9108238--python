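"""Rigid co-registration of follow-up surfaces to a baseline surface.

Point-to-point iterative closest point (ICP): alternate nearest-neighbour
correspondence with the closed-form least-squares rigid fit (SVD with
reflection correction, no scaling). Initialization aligns centroids and
principal axes, disambiguating axis signs by the lowest starting RMS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .mesh_io import SurfaceMesh

ORTHO_TOL = 1e-9
DEFAULT_TOL_MM = 1e-6
DEFAULT_MAX_ITER = 200
SUBSAMPLE_ABOVE = 50_000


class DegenerateSourceError(ValueError):
    """Source cloud is collinear/coplanar: the rigid fit is not unique."""


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation 3x3, det +1; translation mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation is not orthonormal (|R^T R - I| = {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has det -1 (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_rad: float, translation=(0.0, 0.0, 0.0)):
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
        return cls(R, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_rad(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(),
                "translation": self.translation.tolist(), "units": "mm"}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ICPResult:
    transform: RigidTransform
    rms_mm: float
    n_iter: int
    converged: bool
    rms_history: list

    def __iter__(self):  # (transform, rms, n_iter) unpacking
        return iter((self.transform, self.rms_mm, self.n_iter))


def _fit_rigid(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid fit of matched point sets (Kabsch/
    Umeyama without scaling), with reflection correction."""
    mu_s = source.mean(axis=0)
    mu_t = target.mean(axis=0)
    H = (source - mu_s).T @ (target - mu_t)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_s
    return RigidTransform(R, t)


def _principal_axes(points: np.ndarray):
    cov = np.cov(points.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


def _initial_candidates(source: np.ndarray, target: np.ndarray):
    """Centroid + principal-axes alignments: the four proper rotations mapping
    the source axes onto the target axes (axis sign flips in pairs keep
    det = +1), in lexicographic flip order, plus plain centroid alignment."""
    mu_s = source.mean(axis=0)
    mu_t = target.mean(axis=0)
    _, A_s = _principal_axes(source)
    _, A_t = _principal_axes(target)
    if np.linalg.det(A_s) < 0:
        A_s[:, 2] *= -1
    if np.linalg.det(A_t) < 0:
        A_t[:, 2] *= -1
    cands = [RigidTransform(np.eye(3), mu_t - mu_s)]
    for flips in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        R = A_t @ np.diag(flips) @ A_s.T
        cands.append(RigidTransform(R, mu_t - R @ mu_s))
    return cands


def icp_rigid(source: np.ndarray, target: np.ndarray,
              max_iter: int = DEFAULT_MAX_ITER,
              tol: float = DEFAULT_TOL_MM) -> ICPResult:
    """Register ``source`` onto ``target`` (point clouds, mm) by point-to-point
    ICP.

    Iterates nearest-neighbour matching against a KD-tree of the target and
    the SVD rigid fit until the RMS improvement drops below ``tol`` (mm) or
    ``max_iter`` is reached. Deterministic; sources above 50k points are
    stride-subsampled for correspondence but the returned RMS is over all
    points. Raises :class:`DegenerateSourceError` for collinear/coplanar
    sources, where the rotation is not identifiable.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if len(source) < 4:
        raise DegenerateSourceError("need at least 4 source points")
    evals, _ = _principal_axes(source)
    if evals[2] < 1e-12 * max(evals[0], 1.0):
        raise DegenerateSourceError("source points are coplanar or collinear")

    tree = cKDTree(target)
    if len(source) > SUBSAMPLE_ABOVE:
        stride = int(np.ceil(len(source) / SUBSAMPLE_ABOVE))
        work = source[::stride]
    else:
        work = source

    def rms_of(transform, pts):
        d, _ = tree.query(transform.apply(pts))
        return float(np.sqrt(np.mean(d ** 2)))

    best = min(_initial_candidates(work, target), key=lambda tr: rms_of(tr, work))
    current = best
    prev_rms = rms_of(current, work)
    history = [prev_rms]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        moved = current.apply(work)
        _, idx = tree.query(moved)
        current = _fit_rigid(work, target[idx])
        rms = rms_of(current, work)
        history.append(rms)
        if abs(prev_rms - rms) < tol:
            converged = True
            prev_rms = rms
            break
        prev_rms = rms
    final_rms = rms_of(current, source)
    return ICPResult(current, final_rms, n_iter, converged, history)


def apply_transform(mesh: SurfaceMesh, t: RigidTransform) -> SurfaceMesh:
    """Map mesh vertices x -> R x + t; topology, volumes and slice metrics are
    unchanged by construction."""
    out = mesh.copy(vertices=t.apply(mesh.vertices))
    if mesh.vertex_normals is not None:
        out.vertex_normals = mesh.vertex_normals @ t.rotation.T
    return out
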