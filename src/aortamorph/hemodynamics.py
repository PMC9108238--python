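"""Functional (hemodynamic) indicators computed from surface fields and
boundary waveforms.

Wall-shear indicator maps (TAWSS, OSI, RRT), luminal pressure difference (LPD)
between true and false lumen with its first balance position (FBP), total
energy loss of pulsatile flow over one cardiac cycle, per-branch flow
distribution ratios, and circumferential averaging of surface maps along a
centerline. Fields arrive in SI units (Pa, m/s); geometry in mm is converted
internally where the formulas need SI.

Cycle integrals use the trapezoidal rule with a periodic wrap (the sample at
t = T is the first sample again), matching fields discretized at 50 uniform
steps per cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .centerline_morph import Centerline, CrossSection
from .mesh_io import FieldTimeSeries, SurfaceMesh, Waveform

log = logging.getLogger("aortamorph")

#: blood density, kg/m^3 (Newtonian incompressible model)
RHO_BLOOD = 1044.0
#: dynamic viscosity, kg/(m s)
MU_BLOOD = 0.00365
#: temporal discretization, samples per cardiac cycle
STEPS_PER_CYCLE = 50

#: sentinel for an FBP outside the analysed (dissected) extent
FBP_BEYOND = None


def _wrap(series: FieldTimeSeries):
    """Times and values extended so the cycle closes at t = T."""
    t = np.concatenate([series.times_s, [series.period_s]])
    v = np.concatenate([series.values, series.values[:1]], axis=0)
    return t, v


def _cycle_mean(times: np.ndarray, values: np.ndarray, period: float) -> np.ndarray:
    return np.trapezoid(values, times, axis=0) / period


def tawss(wss: FieldTimeSeries) -> np.ndarray:
    """Time-averaged wall shear stress magnitude, (1/T) * int_0^T |tau| dt (Pa)."""
    if wss.kind != "vector3":
        raise TypeError("TAWSS requires a vector WSS series")
    t, v = _wrap(wss)
    mag = np.linalg.norm(v, axis=2)
    return _cycle_mean(t, mag, wss.period_s)


def osi(wss: FieldTimeSeries) -> np.ndarray:
    """Oscillatory shear index, 0.5 * (1 - |int tau dt| / int |tau| dt).

    0 for unidirectional shear, 0.5 for a fully reversing zero-mean shear.
    Vertices with int |tau| dt = 0 (no shear at all) return 0.
    """
    if wss.kind != "vector3":
        raise TypeError("OSI requires a vector WSS series")
    t, v = _wrap(wss)
    mean_vec = np.trapezoid(v, t, axis=0)
    mean_mag = np.trapezoid(np.linalg.norm(v, axis=2), t, axis=0)
    out = np.zeros(wss.n_vertices)
    ok = mean_mag > 0
    out[ok] = 0.5 * (1.0 - np.linalg.norm(mean_vec[ok], axis=1) / mean_mag[ok])
    return np.clip(out, 0.0, 0.5)


def rrt(tawss_map: np.ndarray, osi_map: np.ndarray) -> np.ndarray:
    """Relative residence time, 1 / ((1 - 2*OSI) * TAWSS) (Pa^-1).

    Equals 1/|cycle-mean WSS vector|; +inf where the mean WSS vector vanishes
    (OSI = 0.5 or TAWSS = 0), flagged by the infinity itself.
    """
    tawss_map = np.asarray(tawss_map, dtype=float)
    osi_map = np.asarray(osi_map, dtype=float)
    if tawss_map.shape != osi_map.shape:
        raise ValueError("TAWSS and OSI maps must share vertex count")
    denom = (1.0 - 2.0 * osi_map) * tawss_map
    out = np.full_like(denom, np.inf)
    # denominators at round-off scale mean a vanishing cycle-mean WSS vector
    ok = denom > 1e-12 * np.maximum(tawss_map, 1.0)
    out[ok] = 1.0 / denom[ok]
    return out


@dataclass
class IndicatorMaps:
    """Per-vertex wall-shear indicator maps over one cardiac cycle."""

    tawss_pa: np.ndarray
    osi: np.ndarray
    rrt_pa_inv: np.ndarray
    period_s: float

    @classmethod
    def from_wss(cls, wss: FieldTimeSeries) -> "IndicatorMaps":
        tw = tawss(wss)
        os_ = osi(wss)
        return cls(tw, os_, rrt(tw, os_), wss.period_s)


# ---------------------------------------------------------------------------
# luminal pressure difference
# ---------------------------------------------------------------------------

def slice_average_pressure(mesh: SurfaceMesh, pressure: FieldTimeSeries,
                           sections: Sequence[CrossSection]) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged mean pressure on each cross-section (Pa).

    Per station, pressure is sampled where the slicing plane cuts mesh edges
    (linear interpolation along each cut edge, i.e. inverse-distance weights
    of the edge endpoints) and averaged over those intersection points; the
    result is then cycle-averaged. Returns (stations_mm, pressures_pa);
    stations with no cut edges near the contour are dropped with a log entry.
    """
    if pressure.kind != "scalar":
        raise TypeError("pressure must be a scalar series")
    if pressure.n_vertices != mesh.n_vertices:
        raise ValueError("pressure series does not match mesh vertex count")
    edges = _unique_edges(mesh.faces)
    t_ext = np.concatenate([pressure.times_s, [pressure.period_s]])
    v_ext = np.concatenate([pressure.values, pressure.values[:1]], axis=0)
    out_s, out_p = [], []
    for cs in sections:
        d = (mesh.vertices - cs.origin) @ cs.normal
        e0, e1 = edges[:, 0], edges[:, 1]
        cut = d[e0] * d[e1] < 0
        # a vertex lying exactly in the plane (a mesh ring coinciding with a
        # station) is itself a sample point
        on_plane = np.flatnonzero(np.abs(d) < 1e-9)
        if not np.any(cut) and len(on_plane) == 0:
            log.info("slice_average_pressure: station %.3f mm has no cut edges, dropped", cs.s_mm)
            continue
        a, b = e0[cut], e1[cut]
        wa = np.abs(d[b]) / (np.abs(d[a]) + np.abs(d[b])) if len(a) else np.empty(0)
        pts = (wa[:, None] * mesh.vertices[a] + (1 - wa)[:, None] * mesh.vertices[b]
               if len(a) else np.empty((0, 3)))
        pts = np.vstack([pts, mesh.vertices[on_plane]])
        # restrict to the primary contour's neighbourhood (a curved vessel's
        # plane can cut the lumen far away as well)
        prim = cs.primary
        r_max = np.linalg.norm(prim - cs.origin, axis=1).max()
        keep = np.linalg.norm(pts - cs.origin, axis=1) <= 1.5 * r_max + 1e-9
        if not np.any(keep):
            log.info("slice_average_pressure: station %.3f mm contour unmatched, dropped", cs.s_mm)
            continue
        keep_e = keep[:len(a)]
        keep_v = keep[len(a):]
        a, b, wa = a[keep_e], b[keep_e], wa[keep_e]
        vp = on_plane[keep_v]
        p_edges = (wa[None, :] * v_ext[:, a] + (1 - wa)[None, :] * v_ext[:, b]
                   if len(a) else np.empty((len(t_ext), 0)))
        p_t = np.concatenate([p_edges, v_ext[:, vp]], axis=1)
        spatial_mean = p_t.mean(axis=1)
        out_s.append(cs.s_mm)
        out_p.append(np.trapezoid(spatial_mean, t_ext) / pressure.period_s)
    return np.asarray(out_s), np.asarray(out_p)


def _unique_edges(faces: np.ndarray) -> np.ndarray:
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


@dataclass
class LPDProfile:
    """Luminal pressure difference P_TL - P_FL along the TL centerline."""

    stations_mm: np.ndarray
    p_tl_pa: np.ndarray
    p_fl_pa: np.ndarray
    lpd_pa: np.ndarray = field(init=False)

    def __post_init__(self):
        self.stations_mm = np.asarray(self.stations_mm, dtype=float)
        self.p_tl_pa = np.asarray(self.p_tl_pa, dtype=float)
        self.p_fl_pa = np.asarray(self.p_fl_pa, dtype=float)
        if not (len(self.stations_mm) == len(self.p_tl_pa) == len(self.p_fl_pa)):
            raise ValueError("station/pressure arrays must share length")
        if np.any(np.diff(self.stations_mm) <= 0):
            raise ValueError("stations must be increasing")
        self.lpd_pa = self.p_tl_pa - self.p_fl_pa


def lpd_profile(tl_pressures, fl_pressures, stations) -> LPDProfile:
    """LPD(s) = P_TL(s) - P_FL(s) on common stations."""
    return LPDProfile(np.asarray(stations), np.asarray(tl_pressures),
                      np.asarray(fl_pressures))


def first_balance_position(p: LPDProfile) -> Optional[float]:
    """Most proximal arc-length (mm) where the LPD changes sign, by linear
    interpolation between the bracketing stations.

    A station with LPD exactly 0 is itself the FBP. Returns the sentinel
    ``None`` ("beyond the dissected region") when the sign never changes.
    """
    lpd = p.lpd_pa
    s = p.stations_mm
    if len(s) < 2:
        raise ValueError("need at least 2 stations")
    zero = np.flatnonzero(lpd == 0.0)
    sign_change = np.flatnonzero(np.sign(lpd[:-1]) * np.sign(lpd[1:]) < 0)
    first_zero = s[zero[0]] if len(zero) else np.inf
    if len(sign_change):
        i = sign_change[0]
        crossing = s[i] + (s[i + 1] - s[i]) * lpd[i] / (lpd[i] - lpd[i + 1])
    else:
        crossing = np.inf
    best = min(first_zero, crossing)
    return FBP_BEYOND if np.isinf(best) else float(best)


# ---------------------------------------------------------------------------
# energy loss
# ---------------------------------------------------------------------------

@dataclass
class FlowBoundary:
    """One open boundary of the lumen: area-averaged normal velocity and
    static pressure over a cycle, with its cross-sectional area."""

    label: str
    kind: str  # 'inlet' | 'outlet'
    times_s: np.ndarray
    velocity_m_s: np.ndarray
    pressure_pa: np.ndarray
    area_m2: float

    def __post_init__(self):
        if self.kind not in ("inlet", "outlet"):
            raise ValueError(f"boundary kind must be inlet/outlet, got {self.kind!r}")
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.velocity_m_s = np.asarray(self.velocity_m_s, dtype=float)
        self.pressure_pa = np.asarray(self.pressure_pa, dtype=float)
        if self.area_m2 <= 0:
            raise ValueError("boundary area must be positive")


@dataclass
class EnergyLossResult:
    """Cycle-averaged total energy loss EL = sum_in <TP*Q> - sum_out <TP*Q> (W),
    with TP = 1/2 rho |u|^2 + P the total pressure."""

    el_w: float
    per_boundary_w: dict
    rho_kg_m3: float
    negative_warning: bool = False


def energy_loss(boundaries: Sequence[FlowBoundary], rho: float = RHO_BLOOD,
                period_s: Optional[float] = None) -> EnergyLossResult:
    """Total energy loss of pulsatile flow over one cardiac cycle.

    Per boundary, TP(t) = 1/2 rho u(t)^2 + P(t) and Q(t) = u(t) * A; the loss
    is the cycle average of the inlet total-pressure flux minus the outlet
    flux. A negative result is returned with a warning flag (it usually means
    a mislabeled boundary).
    """
    if not boundaries:
        raise ValueError("no boundaries supplied")
    labels = [b.label for b in boundaries]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate boundary labels")
    if not any(b.kind == "inlet" for b in boundaries):
        raise ValueError("missing inlet boundary")
    if period_s is None:
        period_s = float(max(b.times_s[-1] for b in boundaries))
    per = {}
    total = 0.0
    for b in boundaries:
        tp = 0.5 * rho * b.velocity_m_s ** 2 + b.pressure_pa
        q = b.velocity_m_s * b.area_m2
        t = b.times_s
        if t[-1] < period_s - 1e-12:  # periodic wrap
            t = np.concatenate([t, [period_s]])
            flux = np.concatenate([tp * q, [(tp * q)[0]]])
        else:
            flux = tp * q
        mean_flux = float(np.trapezoid(flux, t) / period_s)
        per[b.label] = mean_flux if b.kind == "inlet" else -mean_flux
        total += per[b.label]
    neg = total < 0
    if neg:
        log.warning("energy_loss is negative (%.4g W): check inlet/outlet labels", total)
    return EnergyLossResult(el_w=total, per_boundary_w=per, rho_kg_m3=rho,
                            negative_warning=neg)


# ---------------------------------------------------------------------------
# flow distribution
# ---------------------------------------------------------------------------

@dataclass
class FlowDistribution:
    """Per-branch cycle-averaged flow fraction of the aortic inflow."""

    ratios: dict
    inflow_m3_s: float


def flow_distribution(inflow: tuple[Waveform, float],
                      branches: Sequence[tuple[str, Waveform, float]]
                      ) -> FlowDistribution:
    """ratio_b = <u_b * A_b> / <u_in * A_in>, cycle means (areas in m^2).

    The velocity traces are treated as plug (area-uniform) profiles, the
    natural reading of a Doppler maximum-velocity trace scaled by a
    user-chosen shape factor applied upstream.
    """
    w_in, a_in = inflow
    q_in = w_in.cycle_mean() * a_in
    if q_in == 0:
        raise ZeroDivisionError("zero cycle-mean inflow")
    ratios = {}
    for label, w, a in branches:
        ratios[label] = w.cycle_mean() * a / q_in
    return FlowDistribution(ratios=ratios, inflow_m3_s=q_in)


# ---------------------------------------------------------------------------
# circumferential averaging
# ---------------------------------------------------------------------------

def circumferential_average(field_map: np.ndarray, mesh: SurfaceMesh,
                            c: Centerline, interval_mm: float = 1.0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Average a per-vertex map over circumferences orthogonal to the
    centerline, every ``interval_mm``.

    Vertices are binned to their nearest centerline station by projecting
    onto arc length; empty bins are reported as NaN. Returns
    (stations_mm, profile).
    """
    field_map = np.asarray(field_map, dtype=float)
    if len(field_map) != mesh.n_vertices:
        raise ValueError("field does not match mesh vertex count")
    dense = c.resampled(min(interval_mm, 0.5))
    from scipy.spatial import cKDTree
    tree = cKDTree(dense.points)
    _, idx = tree.query(mesh.vertices)
    s_vertex = dense.arclength_mm[idx]
    n = int(np.floor(c.length_mm / interval_mm + 1e-9)) + 1
    stations = np.arange(n) * interval_mm
    which = np.clip(np.round(s_vertex / interval_mm).astype(int), 0, n - 1)
    profile = np.full(n, np.nan)
    finite = np.isfinite(field_map)
    for i in range(n):
        sel = (which == i) & finite
        if np.any(sel):
            profile[i] = field_map[sel].mean()
    return stations, profile
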