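"""Surfaces, field time-series, waveforms: in-memory containers and disk I/O.

Conventions: geometry lives in millimetres on disk and in the mesh containers;
hemodynamic formulas convert to SI internally. Vertex indices are 0-based
everywhere. Field tables are plain CSV with a JSON sidecar (units, period) so
fixtures stay inspectable and diff-able.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import trimesh

log = logging.getLogger("aortamorph")

WELD_TOL_MM = 1e-6


class FormatError(ValueError):
    """Raised when a file does not match the expected on-disk format."""


@dataclass
class SurfaceMesh:
    """Closed triangulated lumen boundary in mm.

    ``label`` tags the anatomical region (TL, FL, MAGR, a branch name);
    ``provenance`` tags the timepoint (e.g. Pre-1, Post-1, Post-2).
    ``vertex_normals`` may carry analytic outward normals from a phantom
    generator; otherwise area-weighted normals from the triangulation are used.
    ``metadata`` carries generator ground truth (radius, axis, ...) when known.
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: Optional[str] = None
    provenance: Optional[str] = None
    vertex_normals: Optional[np.ndarray] = None
    manifold: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        self._tm = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def as_trimesh(self) -> trimesh.Trimesh:
        if self._tm is None:
            self._tm = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._tm

    @property
    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def outward_normals(self) -> np.ndarray:
        if self.vertex_normals is not None:
            return self.vertex_normals
        return np.asarray(self.as_trimesh().vertex_normals)

    def copy(self, **updates) -> "SurfaceMesh":
        kw = dict(
            vertices=self.vertices.copy(),
            faces=self.faces.copy(),
            label=self.label,
            provenance=self.provenance,
            vertex_normals=None if self.vertex_normals is None else self.vertex_normals.copy(),
            manifold=self.manifold,
            metadata=dict(self.metadata),
        )
        kw.update(updates)
        return SurfaceMesh(**kw)


def read_surface(path, label: Optional[str] = None,
                 provenance: Optional[str] = None) -> SurfaceMesh:
    """Load an STL surface (ASCII or binary), weld duplicate vertices and drop
    degenerate/duplicate facets.

    A mesh that remains non-manifold after welding is returned with
    ``manifold=False`` and a warning rather than rejected.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"unreadable or empty surface file: {path}")
    try:
        tm = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # pragma: no cover - trimesh error paths
        raise FormatError(f"cannot parse STL {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise FormatError(f"no triangles in {path}")
    n_raw = len(tm.faces)
    tm.merge_vertices(digits_vertex=int(-np.log10(WELD_TOL_MM)))
    tm.update_faces(tm.nondegenerate_faces())
    tm.update_faces(tm.unique_faces())
    n_dropped = n_raw - len(tm.faces)
    if n_dropped:
        log.info("read_surface(%s): removed %d degenerate/duplicate facets", path.name, n_dropped)
    manifold = bool(tm.is_watertight)
    if not manifold:
        warnings.warn(f"{path.name}: surface is not 2-manifold after welding")
    if tm.is_watertight and tm.volume < 0:
        tm.invert()
    mesh = SurfaceMesh(tm.vertices, tm.faces, label=label, provenance=provenance,
                       manifold=manifold)
    mesh.metadata["removed_facets"] = n_dropped
    return mesh


def write_surface(mesh: SurfaceMesh, path) -> None:
    """Write binary STL."""
    mesh.as_trimesh().export(str(path), file_type="stl")


# ---------------------------------------------------------------------------
# field time series
# ---------------------------------------------------------------------------

@dataclass
class FieldTimeSeries:
    """Per-vertex scalar or 3-vector samples over one cardiac cycle.

    ``values`` has shape (n_times, n_vertices) for scalars and
    (n_times, n_vertices, 3) for vectors. ``times_s`` starts at 0 and lies in
    [0, period_s); the sample at t = period_s is the wrap of the first one.
    """

    field_name: str
    kind: str  # 'scalar' | 'vector3'
    values: np.ndarray
    times_s: np.ndarray
    period_s: float
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.kind not in ("scalar", "vector3"):
            raise ValueError(f"unknown field kind {self.kind!r}")
        if self.kind == "scalar" and self.values.ndim != 2:
            raise ValueError("scalar series must be (n_times, n_vertices)")
        if self.kind == "vector3" and (self.values.ndim != 3 or self.values.shape[2] != 3):
            raise ValueError("vector series must be (n_times, n_vertices, 3)")
        if len(self.times_s) < 2:
            raise ValueError("need at least 2 timesteps")
        if self.times_s[0] != 0.0:
            raise ValueError("times must start at 0")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.period_s <= 0:
            raise ValueError("period must be positive")
        if len(self.times_s) != len(self.values):
            raise ValueError("times/values length mismatch")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[1]

    def scaled(self, factor: float) -> "FieldTimeSeries":
        return FieldTimeSeries(self.field_name, self.kind, self.values * factor,
                               self.times_s.copy(), self.period_s, self.units)


def write_field_table(series: FieldTimeSeries, path) -> None:
    """CSV ``vertex,t,value`` (scalar) or ``vertex,t,vx,vy,vz`` (vector), one
    row per (vertex, timestep), plus a ``.json`` sidecar with units/period."""
    path = Path(path)
    nt, nv = series.values.shape[:2]
    vert = np.tile(np.arange(nv), nt)
    t = np.repeat(series.times_s, nv)
    if series.kind == "scalar":
        df = pd.DataFrame({"vertex": vert, "t": t,
                           "value": series.values.reshape(nt * nv)})
    else:
        flat = series.values.reshape(nt * nv, 3)
        df = pd.DataFrame({"vertex": vert, "t": t, "vx": flat[:, 0],
                           "vy": flat[:, 1], "vz": flat[:, 2]})
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {"field_name": series.field_name, "kind": series.kind,
               "units": series.units, "period_s": series.period_s,
               "n_timesteps": nt, "n_vertices": nv}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True))


def read_field_table(path, kind: Optional[str] = None) -> FieldTimeSeries:
    """Read a field table written by :func:`write_field_table`.

    Rows may be in any order; the grid must be complete (every vertex at every
    timestep) or a :class:`FormatError` names the first gap. Passing ``kind``
    enforces scalar/vector; a mismatch is a format error.
    """
    path = Path(path)
    side_path = path.with_suffix(path.suffix + ".json")
    if not side_path.exists():
        raise FormatError(f"missing sidecar {side_path}")
    side = json.loads(side_path.read_text())
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[:2] != ["vertex", "t"]:
        raise FormatError(f"{path}: expected columns starting vertex,t got {cols}")
    file_kind = "scalar" if cols[2:] == ["value"] else (
        "vector3" if cols[2:] == ["vx", "vy", "vz"] else None)
    if file_kind is None:
        raise FormatError(f"{path}: unrecognised value columns {cols[2:]}")
    if kind is not None and kind != file_kind:
        raise FormatError(f"{path}: contains a {file_kind} field, expected {kind}")
    times = np.sort(df["t"].unique())
    verts = np.sort(df["vertex"].unique())
    nt, nv = len(times), len(verts)
    if not np.array_equal(verts, np.arange(nv)):
        raise FormatError(f"{path}: vertex indices are not contiguous from 0")
    if len(df) != nt * nv:
        counts = df.groupby("t")["vertex"].nunique()
        bad_t = counts[counts != nv]
        where = f"t={bad_t.index[0]}" if len(bad_t) else "unknown location"
        raise FormatError(f"{path}: incomplete (vertex, timestep) grid at {where}")
    df = df.sort_values(["t", "vertex"], kind="mergesort")
    if file_kind == "scalar":
        values = df["value"].to_numpy().reshape(nt, nv)
    else:
        values = df[["vx", "vy", "vz"]].to_numpy().reshape(nt, nv, 3)
    return FieldTimeSeries(side.get("field_name", path.stem), file_kind, values,
                           times, float(side["period_s"]), side.get("units", ""))


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

@dataclass
class Waveform:
    """A one-cycle velocity (or flow) trace at a named site, as extracted from
    the upper edge of a Doppler sonogram."""

    times_s: np.ndarray
    velocity_m_s: np.ndarray
    period_s: float
    site: str = ""

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.velocity_m_s = np.asarray(self.velocity_m_s, dtype=float)
        if self.period_s <= 0:
            raise ValueError("period must be positive")
        if np.any(np.diff(self.times_s) <= 0):
            raise FormatError("waveform times must be strictly increasing")
        if self.times_s[0] < 0 or self.times_s[-1] > self.period_s + 1e-12:
            raise ValueError("waveform times must lie within [0, period]")
        if not np.all(np.isfinite(self.velocity_m_s)):
            raise ValueError("waveform has non-finite values")

    def resample(self, n: int) -> "Waveform":
        """Periodic interpolation onto n uniform samples in [0, T).

        Uses a periodic cubic spline (the first sample wraps to t = T), whose
        accuracy on smooth Doppler traces is far better than linear
        interpolation at the same sample count.
        """
        from scipy.interpolate import CubicSpline
        t0 = self.times_s[0]
        t_ext = np.concatenate([self.times_s, [t0 + self.period_s]])
        v_ext = np.concatenate([self.velocity_m_s, [self.velocity_m_s[0]]])
        spline = CubicSpline(t_ext, v_ext, bc_type="periodic")
        t_new = np.arange(n) * self.period_s / n
        v_new = spline(t0 + np.mod(t_new - t0, self.period_s))
        return Waveform(t_new, v_new, self.period_s, self.site)

    def cycle_mean(self) -> float:
        """Time average over one period (trapezoid, periodic wrap)."""
        t_ext = np.concatenate([self.times_s, [self.times_s[0] + self.period_s]])
        v_ext = np.concatenate([self.velocity_m_s, [self.velocity_m_s[0]]])
        return float(np.trapezoid(v_ext, t_ext) / self.period_s)


def read_waveform(path, period_s: Optional[float] = None, site: str = "") -> Waveform:
    """Read a two-column ``time,velocity`` CSV (seconds, m/s).

    If ``period_s`` is not given it is read from a ``.json`` sidecar when one
    exists, else taken as the last time sample.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need two columns time,velocity")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: non-monotone time column")
    if period_s is None:
        side = path.with_suffix(path.suffix + ".json")
        if side.exists():
            period_s = float(json.loads(side.read_text())["period_s"])
        else:
            period_s = float(t[-1])
    # drop a closing duplicate sample at t == period
    if t[-1] >= period_s - 1e-12:
        t, v = t[:-1], v[:-1]
    return Waveform(t, v, period_s, site=site)


def write_waveform(w: Waveform, path) -> None:
    path = Path(path)
    pd.DataFrame({"t": w.times_s, "velocity": w.velocity_m_s}).to_csv(
        path, index=False, float_format="%.17g")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"period_s": w.period_s, "site": w.site}, indent=1, sort_keys=True))


def period_from_heart_rate(beats_per_min: float) -> float:
    """Cardiac period in seconds from a heart rate in beats/min."""
    if beats_per_min <= 0:
        raise ValueError("heart rate must be positive")
    return 60.0 / beats_per_min
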