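"""Case orchestration: register -> morphometry -> indicators -> evolution.

A case is a JSON config listing timepoints (surfaces per region, field
tables, boundary waveforms) plus analysis parameters whose defaults mirror
the fluid constants and cycle timing of the underlying study (blood density
1044 kg/m^3, viscosity 0.00365 Pa s, 50 steps per cycle). ``run_pipeline``
writes per-stage CSV/JSON outputs and a manifest; re-running a config
overwrites the outputs deterministically.

``make_phantom_case`` emits a complete two-timepoint synthetic case — an
expanded, rigidly displaced follow-up with attenuated fields — with its
ground truth, so the whole analysis graph can be exercised end to end
without patient data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import hemodynamics as hd
from .centerline_morph import extract_centerline, morphometry_table, slice_sections
from .evolution import correspond, delta_field, normal_deformation_index
from .mesh_io import (FieldTimeSeries, SurfaceMesh, read_field_table, read_surface,
                      read_waveform, write_field_table, write_surface, write_waveform,
                      Waveform)
from .phantom import (FieldSpec, PhantomSpec, PERIOD_POST_S, deform_phantom,
                      make_dissected_phantom, make_field_series, make_tube)
from .registration import RigidTransform, apply_transform, icp_rigid

log = logging.getLogger("aortamorph")

DEFAULT_PARAMETERS = {
    "slice_interval_mm": 1.0,
    "rho_kg_m3": hd.RHO_BLOOD,
    "mu_pa_s": hd.MU_BLOOD,
    "steps_per_cycle": hd.STEPS_PER_CYCLE,
    "icp_tol_mm": 1e-6,
    "icp_max_iter": 200,
    "sign_convention": "as_described",
    "ray_cutoff_mm": 10.0,
    "velocity_shape_factor": 1.0,
}


class ConfigError(ValueError):
    """The case configuration is invalid or references missing files."""


@dataclass
class CaseConfig:
    """Validated pipeline configuration (see module docstring)."""

    case_name: str
    output_dir: Path
    timepoints: list
    parameters: dict = field(default_factory=dict)
    seed: int = 0
    base_dir: Path = Path(".")

    def __post_init__(self):
        if not self.timepoints:
            raise ConfigError("need at least one timepoint")
        p = dict(DEFAULT_PARAMETERS)
        p.update(self.parameters)
        self.parameters = p
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_json(cls, path) -> "CaseConfig":
        path = Path(path)
        try:
            raw = json.loads(path.read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        for key in ("case_name", "timepoints"):
            if key not in raw:
                raise ConfigError(f"config missing required key {key!r}")
        out_dir = Path(raw.get("output_dir", "out"))
        if not out_dir.is_absolute():
            out_dir = path.parent / out_dir
        return cls(case_name=raw["case_name"],
                   output_dir=out_dir,
                   timepoints=raw["timepoints"],
                   parameters=raw.get("parameters", {}),
                   seed=int(raw.get("seed", 0)),
                   base_dir=path.parent)

    def resolve(self, rel) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, allow_nan=True,
                               default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _map_csv(path: Path, **columns) -> None:
    pd.DataFrame(columns).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: CaseConfig) -> dict:
    """Run every stage the config's inputs support; returns the manifest.

    Stages with missing inputs (e.g. no field tables) are skipped with a log
    entry, not failed. Any stage exception propagates after the manifest is
    written with a stage marker, so partial outputs stay on disk.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    params = config.parameters
    manifest = {"case_name": config.case_name, "parameters": params,
                "stages": {}, "inputs": {}, "outputs": []}
    stage = "load"
    try:
        tps = [_load_timepoint(config, tp_cfg, manifest) for tp_cfg in config.timepoints]
        manifest["stages"]["load"] = [tp["label"] for tp in tps]

        stage = "registration"
        _stage_registration(tps, params, out, manifest)
        stage = "morphometry"
        _stage_morphometry(tps, params, out, manifest)
        stage = "hemodynamics"
        _stage_hemodynamics(tps, params, out, manifest)
        stage = "evolution"
        _stage_evolution(tps, params, out, manifest)
    except Exception:
        manifest["failed_stage"] = stage
        _dump_json(manifest, out / "manifest.json")
        raise
    _write_summary(tps, out, manifest)
    _dump_json(manifest, out / "manifest.json")
    return manifest


def _load_timepoint(config: CaseConfig, tp_cfg: dict, manifest: dict) -> dict:
    label = tp_cfg["label"]
    tp = {"label": label, "cfg": tp_cfg, "meshes": {}, "fields": {},
          "period_s": float(tp_cfg.get("period_s", PERIOD_POST_S))}
    for region, rel in tp_cfg.get("surfaces", {}).items():
        path = config.resolve(rel)
        if not path.exists():
            raise ConfigError(f"{label}: surface file {path} not found")
        tp["meshes"][region] = read_surface(path, label=region, provenance=label)
        manifest["inputs"][f"{label}/{region}"] = _sha256(path)
    if not tp["meshes"]:
        raise ConfigError(f"{label}: no surfaces")
    for region, fields in tp_cfg.get("fields", {}).items():
        for fname, rel in fields.items():
            path = config.resolve(rel)
            if not path.exists():
                log.info("%s: field table %s missing, hemodynamics will be partial",
                         label, path)
                continue
            kind = "vector3" if fname == "wss" else "scalar"
            tp["fields"][(region, fname)] = read_field_table(path, kind=kind)
            manifest["inputs"][f"{label}/{region}.{fname}"] = _sha256(path)
    tp["boundaries_cfg"] = tp_cfg.get("boundaries", [])
    tp["seeds"] = tp_cfg.get("seeds", {})
    tp["base_dir"] = config.base_dir
    return tp


def _combined_vertices(tp: dict) -> np.ndarray:
    return np.vstack([m.vertices for m in tp["meshes"].values()])


def _stage_registration(tps, params, out: Path, manifest) -> None:
    """ICP-align every follow-up timepoint onto the first (baseline)."""
    baseline = tps[0]
    tps[0]["transform"] = RigidTransform.identity()
    records = {}
    for tp in tps[1:]:
        res = icp_rigid(_combined_vertices(tp), _combined_vertices(baseline),
                        max_iter=int(params["icp_max_iter"]),
                        tol=float(params["icp_tol_mm"]))
        tp["transform"] = res.transform
        for region in tp["meshes"]:
            tp["meshes"][region] = apply_transform(tp["meshes"][region], res.transform)
        path = out / f"register_{tp['label']}.json"
        payload = res.transform.to_dict()
        payload.update({"rms_mm": res.rms_mm, "n_iter": res.n_iter,
                        "converged": res.converged})
        _dump_json(payload, path)
        manifest["outputs"].append(path.name)
        records[tp["label"]] = res.rms_mm
    manifest["stages"]["registration"] = records


def _stage_morphometry(tps, params, out: Path, manifest) -> None:
    records = {}
    for tp in tps:
        for region, mesh in tp["meshes"].items():
            seeds = tp["seeds"].get(region)
            if seeds is None:
                continue
            prox = tp["transform"].apply(np.asarray(seeds["proximal"], float)[None, :])[0]
            dist = tp["transform"].apply(np.asarray(seeds["distal"], float)[None, :])[0]
            cl = extract_centerline(mesh, prox, dist,
                                    step_mm=float(params["slice_interval_mm"]))
            tp.setdefault("centerlines", {})[region] = cl
            table = morphometry_table(mesh, cl,
                                      interval_mm=float(params["slice_interval_mm"]),
                                      region=region)
            base = f"morph_{tp['label']}_{region}"
            table.to_csv(out / f"{base}.csv")
            table.to_json(out / f"{base}.json")
            manifest["outputs"] += [f"{base}.csv", f"{base}.json"]
            records[f"{tp['label']}/{region}"] = table.scalars
    manifest["stages"]["morphometry"] = records


def _stage_hemodynamics(tps, params, out: Path, manifest) -> None:
    records = {}
    for tp in tps:
        label = tp["label"]
        rec = {}
        # indicator maps per region with a WSS series
        for (region, fname), series in list(tp["fields"].items()):
            if fname != "wss":
                continue
            maps = hd.IndicatorMaps.from_wss(series)
            tp.setdefault("indicators", {})[region] = maps
            path = out / f"hemo_{label}_{region}_indicators.csv"
            _map_csv(path, vertex=np.arange(len(maps.tawss_pa)),
                     tawss_pa=maps.tawss_pa, osi=maps.osi, rrt_pa_inv=maps.rrt_pa_inv)
            manifest["outputs"].append(path.name)
            rec[f"{region}/tawss_mean_pa"] = float(np.mean(maps.tawss_pa))
            rec[f"{region}/osi_mean"] = float(np.mean(maps.osi))
        # LPD/FBP when both lumens carry pressure and TL has a centerline
        has = lambda r: (r, "pressure") in tp["fields"]
        cls_ = tp.get("centerlines", {})
        if has("TL") and has("FL") and "TL" in cls_:
            cl = cls_["TL"]
            interval = float(params["slice_interval_mm"])
            s_tl, p_tl = hd.slice_average_pressure(
                tp["meshes"]["TL"], tp["fields"][("TL", "pressure")],
                slice_sections(tp["meshes"]["TL"], cl, interval, "TL"))
            s_fl, p_fl = hd.slice_average_pressure(
                tp["meshes"]["FL"], tp["fields"][("FL", "pressure")],
                slice_sections(tp["meshes"]["FL"], cl, interval, "FL"))
            common, i_tl, i_fl = np.intersect1d(s_tl, s_fl, return_indices=True)
            profile = hd.lpd_profile(p_tl[i_tl], p_fl[i_fl], common)
            fbp = hd.first_balance_position(profile)
            path = out / f"hemo_{label}_lpd.csv"
            _map_csv(path, s_mm=profile.stations_mm, p_tl_pa=profile.p_tl_pa,
                     p_fl_pa=profile.p_fl_pa, lpd_pa=profile.lpd_pa)
            manifest["outputs"].append(path.name)
            rec["fbp_mm"] = fbp
            rec["fbp_cm"] = None if fbp is None else fbp / 10.0
            rec["fbp_beyond_dissected_region"] = fbp is None
            tp["lpd"] = profile
        # energy loss + flow distribution from boundary tables
        if tp["boundaries_cfg"]:
            boundaries, inflow, branches = _load_boundaries(tp, params)
            res = hd.energy_loss(boundaries, rho=float(params["rho_kg_m3"]),
                                 period_s=tp["period_s"])
            rec["energy_loss_w"] = res.el_w
            tp["energy_loss"] = res
            if inflow is not None and branches:
                fd = hd.flow_distribution(inflow, branches)
                rec["flow_distribution"] = fd.ratios
                tp["flow_distribution"] = fd
        if rec:
            _dump_json(rec, out / f"hemo_{label}_summary.json")
            manifest["outputs"].append(f"hemo_{label}_summary.json")
        records[label] = rec
    manifest["stages"]["hemodynamics"] = records


def _load_boundaries(tp, params):
    shape = float(params["velocity_shape_factor"])
    boundaries = []
    inflow = None
    branches = []
    cfg_dir = tp["base_dir"]
    for b in tp["boundaries_cfg"]:
        wf = read_waveform(Path(cfg_dir) / b["waveform"],
                           period_s=tp["period_s"], site=b["label"])
        pw = read_waveform(Path(cfg_dir) / b["pressure"],
                           period_s=tp["period_s"], site=b["label"])
        n = int(params["steps_per_cycle"])
        wf_r = wf.resample(n)
        pw_r = pw.resample(n)
        area_m2 = float(b["area_mm2"]) * 1e-6
        boundaries.append(hd.FlowBoundary(
            label=b["label"], kind=b["kind"], times_s=wf_r.times_s,
            velocity_m_s=shape * wf_r.velocity_m_s,
            pressure_pa=pw_r.velocity_m_s, area_m2=area_m2))
        scaled = Waveform(wf_r.times_s, shape * wf_r.velocity_m_s,
                          wf_r.period_s, wf_r.site)
        if b["kind"] == "inlet" and inflow is None:
            inflow = (scaled, area_m2)
        elif b.get("branch", False):
            branches.append((b["label"], scaled, area_m2))
    return boundaries, inflow, branches


def _stage_evolution(tps, params, out: Path, manifest) -> None:
    records = {}
    for ref, fol in zip(tps[:-1], tps[1:]):
        pair = f"{ref['label']}_to_{fol['label']}"
        for region in ref["meshes"]:
            if region not in fol["meshes"]:
                continue
            a = ref["meshes"][region]
            b = fol["meshes"][region]
            corr = correspond(a, b, cutoff_mm=float(params["ray_cutoff_mm"]))
            index, summary = normal_deformation_index(corr)
            rec = {"normal_deformation": {
                "area_weighted_mean_mm": summary.area_weighted_mean_mm,
                "min_mm": summary.min_mm, "max_mm": summary.max_mm,
                "fraction_positive": summary.fraction_positive,
                "poor_alignment": corr.poor_alignment}}
            columns = {"vertex": np.arange(a.n_vertices),
                       "normal_deformation_mm": index}
            for pname, xa, xb in _paired_fields(ref, fol, region):
                ef = delta_field(xa, xb, corr, parameter=pname,
                                 sign_convention=str(params["sign_convention"]))
                columns[f"delta_{pname}"] = ef.delta
                rec[pname] = {"ar_p": ef.ar_p, "ar_n": ef.ar_n,
                              "mean": float(np.nanmean(ef.delta)),
                              "min": float(np.nanmin(ef.delta)),
                              "max": float(np.nanmax(ef.delta))}
            path = out / f"evolution_{pair}_{region}.csv"
            _map_csv(path, **columns)
            _dump_json(rec, out / f"evolution_{pair}_{region}.json")
            manifest["outputs"] += [path.name, f"evolution_{pair}_{region}.json"]
            records[f"{pair}/{region}"] = rec
    manifest["stages"]["evolution"] = records


def _paired_fields(ref, fol, region):
    """Per-vertex scalar maps present at both timepoints for a region:
    time-averaged pressure and the three wall-shear indicators."""
    out = []
    key = (region, "pressure")
    if key in ref["fields"] and key in fol["fields"]:
        out.append(("pressure_pa",
                    _time_avg(ref["fields"][key]), _time_avg(fol["fields"][key])))
    ia = ref.get("indicators", {}).get(region)
    ib = fol.get("indicators", {}).get(region)
    if ia is not None and ib is not None:
        out += [("tawss_pa", ia.tawss_pa, ib.tawss_pa),
                ("osi", ia.osi, ib.osi),
                ("rrt_pa_inv", ia.rrt_pa_inv, ib.rrt_pa_inv)]
    return out


def _time_avg(series: FieldTimeSeries) -> np.ndarray:
    t = np.concatenate([series.times_s, [series.period_s]])
    v = np.concatenate([series.values, series.values[:1]], axis=0)
    return np.trapezoid(v, t, axis=0) / series.period_s


def _write_summary(tps, out: Path, manifest) -> None:
    lines = [f"case: {manifest['case_name']}", ""]
    for stage, rec in manifest["stages"].items():
        lines.append(f"[{stage}]")
        lines.append(json.dumps(rec, indent=1, sort_keys=True, default=_json_default))
        lines.append("")
    (out / "summary.txt").write_text("\n".join(lines))
    manifest["outputs"].append("summary.txt")


# ---------------------------------------------------------------------------
# phantom cases
# ---------------------------------------------------------------------------

PRESETS = ("cylinder", "arch", "dissection")

_R_MM = 10.0
_L_MM = 100.0
_GROWTH_MM = 0.5
_ATTENUATION = 0.8
_SEPTUM_FRACTION = 0.55
_TEARS_MM = (20.0, 80.0)
#: TL/FL axial pressure profiles (Pa at s=0, Pa/mm): LPD = 20 - 0.5 s
_P_TL = (2020.0, -1.0)
_P_FL = (2000.0, -0.5)
_FBP_TRUE_MM = 40.0
#: seeds sit 2 mm inside each end, so pipeline arc-lengths start there
_SEED_INSET_MM = 2.0
#: WSS (base, amplitude) Pa per timepoint: the follow-up loses its
#: oscillatory component and gains mean shear, which is what makes all four
#: wall-shear indicators (TAWSS, OSI, RRT and their ΔX) decrease — a pure
#: scale-down cannot (OSI is scale-invariant and RRT rises as TAWSS falls)
_WSS_POST1 = (1.0, 1.5)
_WSS_POST2 = (1.1, 0.3)


def make_phantom_case(out_dir, preset: str = "cylinder", seed: int = 0) -> Path:
    """Write a complete two-timepoint synthetic case directory and return the
    path of its ``case.json``.

    The follow-up timepoint is the baseline surface grown by +0.5 mm along
    its normals, rigidly displaced by a seed-drawn transform (rotation <= 10
    degrees, translation <= 10 mm), with all fields attenuated to 80% — an
    "improving" follow-up: positive wall deformation and decreased
    pressure/WSS parameters everywhere.
    """
    if preset not in PRESETS:
        raise ValueError(f"preset must be one of {PRESETS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    true_t = RigidTransform.from_axis_angle(
        axis, np.deg2rad(rng.uniform(2.0, 10.0)), rng.uniform(-10.0, 10.0, 3))
    period = PERIOD_POST_S
    n_steps = hd.STEPS_PER_CYCLE

    if preset == "dissection":
        spec = PhantomSpec("dissected_segment", radius_mm=_R_MM, length_mm=_L_MM,
                           septum_fraction=_SEPTUM_FRACTION,
                           tear_arclengths_mm=list(_TEARS_MM), seed=seed)
        tl, fl, cl, tears = make_dissected_phantom(spec)
        regions = {"TL": tl, "FL": fl}
        gt_extra = {"tears": tears, "septum_fraction": _SEPTUM_FRACTION,
                    "fbp_axis_mm": _FBP_TRUE_MM,
                    "fbp_from_proximal_seed_mm": _FBP_TRUE_MM - _SEED_INSET_MM}
    else:
        kind = "straight_tube" if preset == "cylinder" else "composite_arch"
        spec = PhantomSpec(kind, radius_mm=_R_MM, length_mm=_L_MM if preset == "cylinder" else 50.0,
                           bend_radius_mm=60.0, arc_angle_deg=120.0, seed=seed)
        mesh, cl = make_tube(spec)
        regions = {"lumen": mesh}
        gt_extra = {}

    def fields_for(mesh: SurfaceMesh, region: str, factor: float) -> dict:
        wss_base, wss_amp = _WSS_POST1 if factor == 1.0 else _WSS_POST2
        wss = make_field_series(
            mesh, FieldSpec("pulsatile_cosine", base_value=wss_base,
                            amplitude=wss_amp, period_s=period,
                            n_timesteps=n_steps, units="Pa"),
            kind="vector3", name="wss")
        if preset == "dissection" and region in ("TL", "FL"):
            base, slope = _P_TL if region == "TL" else _P_FL
            p = make_field_series(
                mesh, FieldSpec("axial_linear", base_value=base * factor,
                                axial_slope=slope * factor, period_s=period,
                                n_timesteps=n_steps, units="Pa"),
                kind="scalar", name="pressure")
        else:
            p = make_field_series(
                mesh, FieldSpec("pulsatile_cosine", base_value=2000.0 * factor,
                                amplitude=400.0 * factor, period_s=period,
                                n_timesteps=n_steps, units="Pa"),
                kind="scalar", name="pressure")
        return {"wss": wss, "pressure": p}

    timepoints = []
    gt = {"true_transform": true_t.to_dict(), "true_growth_mm": _GROWTH_MM,
          "field_attenuation": _ATTENUATION, "preset": preset, "seed": seed,
          "period_s": period, **gt_extra}
    for label, factor, deform in (("Post-1", 1.0, False), ("Post-2", _ATTENUATION, True)):
        tp_meshes = {}
        for region, mesh in regions.items():
            m = deform_phantom(mesh, true_t, _GROWTH_MM) if deform else mesh
            tp_meshes[region] = m
        surfaces, fields_cfg = {}, {}
        for region, m in tp_meshes.items():
            stem = f"{label}_{region}"
            write_surface(m, out_dir / f"{stem}.stl")
            surfaces[region] = f"{stem}.stl"
            fields_cfg[region] = {}
            for fname, series in fields_for(m, region, factor).items():
                write_field_table(series, out_dir / f"{stem}.{fname}.csv")
                fields_cfg[region][fname] = f"{stem}.{fname}.csv"
        boundaries = _phantom_boundaries(out_dir, label, preset, period, n_steps)
        first_region = "TL" if preset == "dissection" else "lumen"
        seeds_pt = {first_region: {
            "proximal": (true_t.apply(np.array([[0.0, 0.0, _SEED_INSET_MM]]))[0].tolist()
                         if deform else [0.0, 0.0, _SEED_INSET_MM]),
            "distal": (true_t.apply(np.array([[0.0, 0.0, cl.length_mm - _SEED_INSET_MM]]))[0].tolist()
                       if deform else [0.0, 0.0, cl.length_mm - _SEED_INSET_MM]),
        }}
        if preset == "arch":
            p0, _ = cl.at(_SEED_INSET_MM)
            p1, _ = cl.at(cl.length_mm - _SEED_INSET_MM)
            seeds_pt = {"lumen": {
                "proximal": (true_t.apply(p0[None, :])[0] if deform else p0).tolist(),
                "distal": (true_t.apply(p1[None, :])[0] if deform else p1).tolist(),
            }}
        timepoints.append({"label": label, "period_s": period,
                           "surfaces": surfaces, "fields": fields_cfg,
                           "seeds": seeds_pt, "boundaries": boundaries})
    config = {"case_name": f"phantom_{preset}", "seed": seed,
              "output_dir": "out", "parameters": {}, "timepoints": timepoints}
    (out_dir / "case.json").write_text(
        json.dumps(config, indent=1, sort_keys=True) + "\n")
    (out_dir / "groundtruth.json").write_text(
        json.dumps(gt, indent=1, sort_keys=True) + "\n")
    return out_dir / "case.json"


def _phantom_boundaries(out_dir: Path, label: str, preset: str,
                        period: float, n_steps: int) -> list:
    """Plug-flow cosine inlet, steady outlet(s); constant boundary pressures
    with a 100 Pa inlet-outlet drop so the energy loss has a closed form."""
    t = np.arange(n_steps) * period / n_steps
    u_in = 0.30 * (1.0 + np.cos(2.0 * np.pi * t / period))
    area_mm2 = np.pi * _R_MM ** 2
    p_in, p_out = 2000.0, 1900.0
    entries = []

    def emit(name, kind, u, p, area, branch=False):
        wpath = out_dir / f"{label}_{name}.waveform.csv"
        ppath = out_dir / f"{label}_{name}.pressure.csv"
        write_waveform(Waveform(t, u, period, site=name), wpath)
        write_waveform(Waveform(t, p, period, site=name), ppath)
        entries.append({"label": name, "kind": kind, "area_mm2": area,
                        "waveform": wpath.name, "pressure": ppath.name,
                        "branch": branch})

    emit("inlet", "inlet", u_in, np.full(n_steps, p_in), area_mm2)
    if preset == "dissection":
        emit("tl_outlet", "outlet", u_in, np.full(n_steps, p_out),
             area_mm2 * _SEPTUM_FRACTION, branch=True)
        emit("fl_outlet", "outlet", u_in, np.full(n_steps, p_out),
             area_mm2 * (1.0 - _SEPTUM_FRACTION), branch=True)
    else:
        emit("outlet", "outlet", u_in, np.full(n_steps, p_out), area_mm2)
    return entries


def expected_phantom_energy_loss_w() -> float:
    """Closed-form energy loss of the phantom boundary set: equal plug
    velocities make the kinetic fluxes cancel, so EL = (P_in - P_out) <Q>."""
    area_m2 = np.pi * (_R_MM * 1e-3) ** 2
    return 100.0 * 0.30 * area_m2
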