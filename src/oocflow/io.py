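"""Config parsing, validated defaults, and bit-stable writers/readers.

Configs speak bench units (mm, ml/min, µm, hours); everything is converted
to SI on read and all output files are SI with unit-suffixed column names.
Floats are serialized with 17 significant digits, so every write-then-read
round-trips to full precision.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import units
from .analysis import ScenarioSummary, summarize
from .flow import FlowField, FluidProperties, flow_metrics, solve_steady_flow
from .geometry import DeviceGeometry, StructuredGrid, rasterize
from .tracer import EnsembleResult, ForceConfig, ParticleProperties, trace_ensemble

__all__ = [
    "RunConfig",
    "config_defaults",
    "load_config",
    "parse_config",
    "write_field_vtk",
    "read_field_vtk",
    "write_trajectories_csv",
    "write_events_csv",
    "write_summary_json",
    "run_pipeline",
]

_FMT = "%.17g"

# The default configuration IS the study condition set: 0.3 ml/min perfusion
# of a water-like medium, NK-cell-sized particles (r=6 µm, ρ=1080 kg/m³),
# a 1.5 ml circuit, 4 h of dynamic co-culture, 1000 traced cells.
_DEFAULTS: dict = {
    "geometry": {
        "mode": "planar_chamber",
        "channel_diameter_mm": 1.0,
        "channel_length_mm": 2.0,
        "chamber_diameter_mm": 16.0,
        "chamber_height_mm": 1.5,
        "membrane_diameter_mm": 6.5,
        "circuit_volume_ml": 1.5,
    },
    "fluid": {
        "density_kg_m3": 1000.0,
        "viscosity_Pa_s": 1.0e-3,
    },
    "flow": {
        "flow_rate_ml_min": 0.3,
        "grid_spacing_um": 50.0,
        "tolerance": 1.0e-6,
        "max_iterations": 50,
        "include_inertia": False,
    },
    "particles": {
        "radius_um": 6.0,
        "density_kg_m3": 1080.0,
        "count": 1000,
    },
    "forces": {
        "drag": True,
        "gravity": True,
        "protrusion_N": 0.0,
        "crossing_probability": 1.0,
        "overdamped": False,
    },
    "run": {
        "duration_h": 4.0,
        "dt_s": 1.0e-3,
        "seed": 0,
        "recirculation": True,
        "trajectory_samples": 10,
    },
}


def config_defaults() -> dict:
    return copy.deepcopy(_DEFAULTS)


def _merge_validated(overrides: dict) -> dict:
    cfg = config_defaults()
    for section, keys in (overrides or {}).items():
        if section not in cfg:
            raise ValueError(
                f"unknown config section {section!r}; valid sections: "
                f"{sorted(cfg)}"
            )
        if not isinstance(keys, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        for key, value in keys.items():
            if section == "run" and key == "static":
                continue  # informational flag, recomputed from the flow rate
            if key not in cfg[section]:
                raise ValueError(
                    f"unknown key {section}.{key}; valid keys: "
                    f"{sorted(cfg[section])}"
                )
            cfg[section][key] = value
    return cfg


@dataclass
class RunConfig:
    """Fully validated run description, SI units."""

    geometry: DeviceGeometry
    fluid: FluidProperties
    particles: ParticleProperties
    forces: ForceConfig
    flow_rate: float  # m³/s
    grid_spacing: float  # m
    tolerance: float
    max_iterations: int
    include_inertia: bool
    n: int
    duration: float  # s
    dt: float  # s
    seed: int
    recirculation: bool
    trajectory_samples: int
    raw: dict

    @property
    def static(self) -> bool:
        """True when the pump is off (flow rate zero)."""
        return self.flow_rate == 0.0


def parse_config(data: dict | None) -> RunConfig:
    """Validate a (possibly partial) config mapping against the defaults."""
    cfg = _merge_validated(data or {})
    g = cfg["geometry"]
    geometry = DeviceGeometry(
        mode=g["mode"],
        channel_diameter=units.length_to_si(g["channel_diameter_mm"], "mm"),
        channel_length=units.length_to_si(g["channel_length_mm"], "mm"),
        chamber_diameter=units.length_to_si(g["chamber_diameter_mm"], "mm"),
        chamber_height=units.length_to_si(g["chamber_height_mm"], "mm"),
        membrane_diameter=units.length_to_si(g["membrane_diameter_mm"], "mm"),
        circuit_volume=units.volume_to_si(g["circuit_volume_ml"], "ml"),
    )
    f = cfg["fluid"]
    fluid = FluidProperties(density=f["density_kg_m3"], viscosity=f["viscosity_Pa_s"])
    p = cfg["particles"]
    particles = ParticleProperties(
        radius=units.length_to_si(p["radius_um"], "um"), density=p["density_kg_m3"]
    )
    fo = cfg["forces"]
    forces = ForceConfig(
        drag=bool(fo["drag"]),
        gravity=bool(fo["gravity"]),
        protrusion_magnitude=float(fo["protrusion_N"]),
        crossing_probability=float(fo["crossing_probability"]),
        overdamped=bool(fo["overdamped"]),
    )
    fl = cfg["flow"]
    if fl["flow_rate_ml_min"] < 0:
        raise ValueError("flow rate must be non-negative")
    r = cfg["run"]
    return RunConfig(
        geometry=geometry,
        fluid=fluid,
        particles=particles,
        forces=forces,
        flow_rate=units.flow_rate_to_si(fl["flow_rate_ml_min"], "ml/min"),
        grid_spacing=units.length_to_si(fl["grid_spacing_um"], "um"),
        tolerance=float(fl["tolerance"]),
        max_iterations=int(fl["max_iterations"]),
        include_inertia=bool(fl["include_inertia"]),
        n=int(p["count"]),
        duration=units.time_to_si(r["duration_h"], "h"),
        dt=float(r["dt_s"]),
        seed=int(r["seed"]),
        recirculation=bool(r["recirculation"]),
        trajectory_samples=int(r["trajectory_samples"]),
        raw=cfg,
    )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return parse_config(data)


# ---- VTK (legacy ASCII structured grid) -----------------------------------


def write_field_vtk(field: FlowField, path: str | Path) -> None:
    """Write the field as a legacy-VTK structured-points file.

    Node-averaged velocity and cell pressure are stored for visualization;
    the raw staggered arrays ride along as FIELD data so a read-back
    reconstructs the solution to full precision.
    """
    g = field.grid
    nx, nz, h = g.nx, g.nz, g.spacing
    # node-averaged velocity (nx+1, nz+1)
    un = np.zeros((nx + 1, nz + 1))
    un[:, 1:-1] = 0.5 * (field.u[:, :-1] + field.u[:, 1:])
    wn = np.zeros((nx + 1, nz + 1))
    wn[1:-1, :] = 0.5 * (field.w[:-1, :] + field.w[1:, :])

    def arr(a: np.ndarray) -> str:
        return "\n".join(_FMT % v for v in np.asarray(a).ravel(order="F"))

    lines = [
        "# vtk DataFile Version 3.0",
        "oocflow steady flow field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {nz + 1} 1",
        "ORIGIN 0 0 0",
        _FMT % h + " " + _FMT % h + " 1",
    ]
    lines[-1] = "SPACING " + lines[-1]
    lines.append(f"POINT_DATA {(nx + 1) * (nz + 1)}")
    lines.append("VECTORS velocity_m_per_s double")
    vx = un.ravel(order="F")
    vz = wn.ravel(order="F")
    lines.extend(f"{_FMT % a} 0 {_FMT % b}" for a, b in zip(vx, vz))
    lines.append(f"CELL_DATA {nx * nz}")
    lines.append("SCALARS pressure_Pa double 1")
    lines.append("LOOKUP_TABLE default")
    lines.append(arr(field.p))
    # staggered arrays for exact reconstruction
    lines.append("FIELD oocflow 5")
    for name, a in (
        ("u_face_m_per_s", field.u),
        ("w_face_m_per_s", field.w),
        ("p_cell_Pa", field.p),
    ):
        flat = np.asarray(a).ravel(order="F")
        lines.append(f"{name} 1 {flat.size} double")
        lines.append("\n".join(_FMT % v for v in flat))
    lines.append("flow_rate_m3_per_s 1 1 double")
    lines.append(_FMT % field.flow_rate)
    lines.append("flux_target 1 1 double")
    lines.append(_FMT % field.flux_target)
    Path(path).write_text("\n".join(lines) + "\n")


def read_field_vtk(path: str | Path, grid: StructuredGrid, fluid: FluidProperties | None = None) -> FlowField:
    """Reconstruct a FlowField written by :func:`write_field_vtk`."""
    tokens = Path(path).read_text().split("\n")
    nx, nz = grid.nx, grid.nz
    arrays: dict[str, np.ndarray] = {}
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        parts = line.split()
        if len(parts) == 4 and parts[0].endswith(("m_per_s", "Pa", "target", "per_s")) and parts[3] == "double":
            name, _, count = parts[0], parts[1], int(parts[2])
            vals: list[float] = []
            i += 1
            while len(vals) < count:
                vals.extend(float(v) for v in tokens[i].split())
                i += 1
            arrays[name] = np.array(vals)
            continue
        i += 1
    u = arrays["u_face_m_per_s"].reshape((nx + 1, nz), order="F")
    w = arrays["w_face_m_per_s"].reshape((nx, nz + 1), order="F")
    p = arrays["p_cell_Pa"].reshape((nx, nz), order="F")
    return FlowField(
        grid=grid,
        fluid=fluid or FluidProperties(),
        u=u,
        w=w,
        p=p,
        flow_rate=float(arrays["flow_rate_m3_per_s"][0]),
        flux_target=float(arrays["flux_target"][0]),
        converged=True,
    )


# ---- CSV / JSON ------------------------------------------------------------


def write_trajectories_csv(result: EnsembleResult, path: str | Path) -> None:
    rows = []
    names = result.status_names()
    for pid, arr in sorted(result.trajectories.items()):
        for t, x, z, vx, vz in arr:
            rows.append((pid, t, x, z, vx, vz, names[pid], result.pass_counts[pid]))
    df = pd.DataFrame(
        rows,
        columns=[
            "particle_id",
            "time_s",
            "x_m",
            "z_m",
            "vx_m_per_s",
            "vz_m_per_s",
            "status",
            "pass_count",
        ],
    )
    df.to_csv(path, index=False, float_format=_FMT)


def write_events_csv(result: EnsembleResult, path: str | Path) -> None:
    df = pd.DataFrame(
        result.events, columns=["particle_id", "time_s", "event", "x_m", "z_m"]
    )
    df.to_csv(path, index=False, float_format=_FMT)


def summary_dict(summary: ScenarioSummary, metrics=None, extra: dict | None = None) -> dict:
    out = {
        "n": summary.n,
        "n_extravasated": summary.n_extravasated,
        "extravasated_fraction": summary.extravasated_fraction,
        "fraction_se": summary.fraction_se,
        "event_time_quantiles_s": {str(k): v for k, v in summary.event_time_quantiles.items()},
        "speed_quantiles_m_per_s": {str(k): v for k, v in summary.speed_quantiles.items()},
        "rebounds": summary.rebounds,
        "membrane_contacts": summary.membrane_contacts,
        "crossings": summary.crossings,
        "recirculations": summary.recirculations,
        "geometry_fingerprint": summary.geometry_fingerprint,
        "config_fingerprint": summary.config_fingerprint,
        "seed": summary.seed,
    }
    if metrics is not None:
        out["flow"] = {
            "max_speed_m_per_s": metrics.max_speed,
            "mean_inlet_speed_m_per_s": metrics.mean_inlet_speed,
            "reynolds": metrics.reynolds,
            "inlet_flux": metrics.inlet_flux,
            "outlet_flux": metrics.outlet_flux,
            "max_divergence_residual": metrics.max_divergence_residual,
            "laminar": metrics.laminar,
        }
    if extra:
        out.update(extra)
    return out


def write_summary_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


# ---- pipeline ---------------------------------------------------------------


def run_pipeline(config: RunConfig | str | Path, out_dir: str | Path) -> dict:
    """solve → trace → analyze; write field.vtk, traj.csv, events.csv, summary.json.

    Deterministic: re-running with the same config and seed reproduces
    summary.json byte for byte.
    """
    if not isinstance(config, RunConfig):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed={config.seed}", f"numpy={np.__version__}"]

    stage = "flow solve"
    try:
        grid = rasterize(config.geometry, config.grid_spacing)
        field = solve_steady_flow(
            grid,
            config.fluid,
            config.flow_rate,
            tolerance=config.tolerance,
            max_iterations=config.max_iterations,
            include_inertia=config.include_inertia,
        )
        metrics = flow_metrics(field, grid, config.fluid)
        log_lines.append(f"flow residuals={field.residual_history}")
        write_field_vtk(field, out / "field.vtk")

        stage = "particle tracing"
        result = trace_ensemble(
            config.geometry,
            field,
            config.particles,
            config.forces,
            n=config.n,
            duration=config.duration,
            dt=config.dt,
            seed=config.seed,
            recirculation=config.recirculation,
            fluid=config.fluid,
            n_trajectory_samples=config.trajectory_samples,
        )
        write_trajectories_csv(result, out / "traj.csv")
        write_events_csv(result, out / "events.csv")

        stage = "analysis"
        summary = summarize(result)
        data = summary_dict(summary, metrics, extra={"static": config.static})
        write_summary_json(data, out / "summary.json")
    except Exception as exc:  # annotate the failing stage, then re-raise
        (out / "run.log").write_text(
            "\n".join(log_lines + [f"FAILED during {stage}: {exc}"]) + "\n"
        )
        raise RuntimeError(f"pipeline failed during {stage}: {exc}") from exc

    (out / "run.log").write_text("\n".join(log_lines + ["status=ok"]) + "\n")
    return {
        "field": out / "field.vtk",
        "trajectories": out / "traj.csv",
        "events": out / "events.csv",
        "summary": out / "summary.json",
        "log": out / "run.log",
    }
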