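"""Benchmark fixtures and run configs, generated from closed forms.

Everything the test suite and the validation CLI need is produced here at
run time: no fixture is downloaded or checked in.  Each benchmark config is
paired with its analytically expected values (Poiseuille peak speed, Stokes
settling speed, ...) computed from the closed-form oracle at generation
time and stored next to the formula string, never as an opaque constant.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import yaml

from .flow import FluidProperties
from .tracer import ParticleProperties, settling_speed
from . import io as _io

__all__ = ["make_benchmark_suite", "generate_run_config"]


def generate_run_config(overrides: dict | None = None) -> str:
    """Render a complete, validated run config as YAML text.

    ``overrides`` is a nested mapping of known sections/keys; unknown keys
    are rejected with the list of valid ones.  The defaults are the study
    conditions: 0.3 ml/min perfusion, water-like medium (ρ = 1000 kg/m³,
    μ = 10⁻³ Pa·s), NK-cell-sized particles (r_p = 6 µm, ρ_p = 1080 kg/m³),
    1.5 ml circuit, 4 h duration.
    """
    cfg = _io.parse_config(overrides or {})  # raises on unknown keys
    data = cfg.raw
    if cfg.static:
        data["run"] = dict(data["run"], static=True)
    return yaml.safe_dump(data, sort_keys=True)


def _expected_tube(q_si: float, radius: float) -> dict:
    u_peak = 2.0 * q_si / (math.pi * radius**2)
    return {
        "max_speed_m_per_s": u_peak,
        "formula": "u_max = 2Q/(pi R^2) for fully developed laminar tube flow",
        "provenance": "closed form",
    }


def _expected_settling() -> dict:
    v_s = settling_speed(ParticleProperties(), FluidProperties())
    h = 1.5e-3
    return {
        "terminal_speed_m_per_s": v_s,
        "floor_crossing_time_s": h / v_s,
        "formula": "v_s = 2 r_p^2 (rho_p - rho) g / (9 mu); T = h / v_s",
        "provenance": "closed form",
    }


def make_benchmark_suite(out_dir: str | Path) -> dict:
    """Write the five benchmark configs and a manifest with expected values.

    (a) Poiseuille tube (Ø 1 mm, 0.3 ml/min) — flow-solver oracle;
    (b) quiescent settling box — gravity/drag oracle;
    (c) uniform-advection duct — drag fixed-point (no body forces);
    (d) reference device, flow only — extravasation null;
    (e) reference device with a 10⁻¹¹ N protrusion force — crossing check.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    q_si = 0.3e-6 / 60.0

    fixtures = {
        "poiseuille_tube": {
            "overrides": {
                "geometry": {
                    "mode": "axisymmetric_tube",
                    "channel_diameter_mm": 1.0,
                    "channel_length_mm": 10.0,
                },
                "run": {"duration_h": 0.0, "seed": 101},
            },
            "expected": _expected_tube(q_si, 0.5e-3),
        },
        "settling_box": {
            "overrides": {
                "geometry": {
                    "channel_diameter_mm": 1.5,
                    "channel_length_mm": 1.0,
                    "chamber_diameter_mm": 5.0,
                    "chamber_height_mm": 1.5,
                    "membrane_diameter_mm": 1.0,
                },
                "flow": {"flow_rate_ml_min": 0.0, "grid_spacing_um": 150.0},
                "particles": {"count": 200},
                "forces": {"overdamped": True},
                "run": {"duration_h": 0.075, "dt_s": 0.01, "seed": 102},
            },
            "expected": _expected_settling(),
        },
        "uniform_advection_duct": {
            "overrides": {
                "geometry": {
                    "channel_diameter_mm": 1.5,
                    "channel_length_mm": 1.0,
                    "chamber_diameter_mm": 5.0,
                    "chamber_height_mm": 1.5,
                    "membrane_diameter_mm": 1.0,
                },
                "flow": {"flow_rate_ml_min": 0.0, "grid_spacing_um": 150.0},
                "forces": {"gravity": False},
                "particles": {"count": 50},
                "run": {"duration_h": 0.001, "dt_s": 0.001, "seed": 103},
            },
            "expected": {
                "note": "with v(0)=u_f and no body force the particle advects "
                "with the fluid exactly",
                "provenance": "fixed point of the drag law",
            },
        },
        "reference_flow_only": {
            "overrides": {
                "forces": {"protrusion_N": 0.0, "overdamped": True},
                "run": {"duration_h": 4.0, "dt_s": 0.02, "seed": 104},
            },
            "expected": {
                "extravasated_fraction": 0.0,
                "max_speed_m_per_s_approx": _expected_tube(q_si, 0.5e-3)[
                    "max_speed_m_per_s"
                ],
                "formula": "no protrusion force => no membrane crossing; "
                "channel peak from Poiseuille",
                "provenance": "model structure + closed form",
            },
        },
        "reference_protrusion": {
            "overrides": {
                "forces": {"protrusion_N": 1.0e-11, "overdamped": True},
                "particles": {"count": 500},
                "run": {"duration_h": 0.5, "dt_s": 0.02, "seed": 105},
            },
            "expected": {
                "extravasated_fraction_positive": True,
                "formula": "protrusion 1e-11 N > buoyant weight 7.1e-13 N "
                "=> net upward force under the membrane",
                "provenance": "force balance",
            },
        },
    }

    manifest: dict = {"fixtures": {}}
    for name, spec in fixtures.items():
        text = generate_run_config(spec["overrides"])
        path = out / f"{name}.yaml"
        path.write_text(text)
        manifest["fixtures"][name] = {
            "config": path.name,
            "expected": spec["expected"],
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
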