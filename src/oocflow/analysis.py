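"""Extravasation analysis: summaries, scenario contrasts, force calibration.

The headline observable is the extravasated fraction — the share of
circulating cells that crossed the membrane into the tumor compartment
within the run.  Flow alone produces a fraction of exactly zero (the net
body force under the membrane points away from it); a protrusion force above
the buoyant weight opens a monotone fraction–force map, which the calibrator
inverts by bisection.  The experimentally observed fraction (around 2 % of
circulating NK cells over a 4 h co-culture) is used strictly as a
calibration anchor: the force the calibrator returns is model-implied, not
measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
import math

import numpy as np

from .flow import FlowField, FluidProperties
from .geometry import DeviceGeometry
from .tracer import (
    EnsembleResult,
    ForceConfig,
    ParticleProperties,
    trace_ensemble,
)

__all__ = [
    "ScenarioSummary",
    "DeltaReport",
    "CalibrationError",
    "summarize",
    "compare_scenarios",
    "calibrate_protrusion",
]

_QUANTILES = (0.1, 0.25, 0.5, 0.75, 0.9)


@dataclass(frozen=True)
class ScenarioSummary:
    """Deterministic digest of one traced ensemble."""

    n: int
    n_extravasated: int
    extravasated_fraction: float
    fraction_se: float  # binomial standard error of the fraction
    event_time_quantiles: dict  # quantile -> crossing time, s (empty if none)
    speed_quantiles: dict  # quantile -> sampled trajectory speed, m/s
    rebounds: int
    membrane_contacts: int
    crossings: int
    recirculations: int
    geometry_fingerprint: str
    config_fingerprint: str
    seed: int


def summarize(ensemble: EnsembleResult) -> ScenarioSummary:
    """Pure summary of an ensemble: same input, identical output."""
    frac = ensemble.extravasated_fraction
    se = math.sqrt(max(frac * (1.0 - frac), 0.0) / ensemble.n)
    times = ensemble.crossing_times[np.isfinite(ensemble.crossing_times)]
    tq = (
        {q: float(np.quantile(times, q)) for q in _QUANTILES} if len(times) else {}
    )
    speeds = []
    for rows in ensemble.trajectories.values():
        if len(rows):
            speeds.append(np.hypot(rows[:, 3], rows[:, 4]))
    sq = {}
    if speeds:
        allspeeds = np.concatenate(speeds)
        sq = {q: float(np.quantile(allspeeds, q)) for q in _QUANTILES}
    return ScenarioSummary(
        n=ensemble.n,
        n_extravasated=ensemble.n_extravasated,
        extravasated_fraction=frac,
        fraction_se=se,
        event_time_quantiles=tq,
        speed_quantiles=sq,
        rebounds=ensemble.counts["rebounds"],
        membrane_contacts=ensemble.counts["membrane_contacts"],
        crossings=ensemble.counts["crossings"],
        recirculations=ensemble.counts["recirculations"],
        geometry_fingerprint=ensemble.geometry_fingerprint,
        config_fingerprint=ensemble.config_fingerprint,
        seed=ensemble.seed,
    )


@dataclass(frozen=True)
class DeltaReport:
    """Paired differences between two scenario summaries (b minus a)."""

    d_fraction: float
    d_event_time_quantiles: dict
    d_speed_quantiles: dict
    seeds: tuple


def compare_scenarios(a: ScenarioSummary, b: ScenarioSummary) -> DeltaReport:
    """Contrast two scenarios run on the same device geometry."""
    if a.geometry_fingerprint != b.geometry_fingerprint:
        raise ValueError(
            "scenario summaries come from different geometries "
            f"({a.geometry_fingerprint} vs {b.geometry_fingerprint})"
        )
    dtq = {
        q: b.event_time_quantiles[q] - a.event_time_quantiles[q]
        for q in a.event_time_quantiles
        if q in b.event_time_quantiles
    }
    dsq = {
        q: b.speed_quantiles[q] - a.speed_quantiles[q]
        for q in a.speed_quantiles
        if q in b.speed_quantiles
    }
    return DeltaReport(
        d_fraction=b.extravasated_fraction - a.extravasated_fraction,
        d_event_time_quantiles=dtq,
        d_speed_quantiles=dsq,
        seeds=(a.seed, b.seed),
    )


class CalibrationError(RuntimeError):
    """Target fraction unreachable in the bracket, or resolution too coarse."""

    def __init__(self, message: str, bracket_fractions: tuple | None = None):
        super().__init__(message)
        self.bracket_fractions = bracket_fractions


def calibrate_protrusion(
    target_fraction: float,
    duration: float,
    n: int,
    seed: int,
    tolerance: float,
    *,
    geometry: DeviceGeometry,
    field: FlowField,
    props: ParticleProperties | None = None,
    forces: ForceConfig | None = None,
    fluid: FluidProperties | None = None,
    dt: float = 0.02,
    bracket: tuple[float, float] = (0.0, 1.0e-10),
    force_resolution: float | None = None,
    history: list | None = None,
) -> float:
    """Invert the fraction–force map by bisection with common random numbers.

    Every fraction evaluation re-traces the same seeded ensemble (common
    random numbers), so the map is a deterministic non-decreasing function
    of the force and bisection is valid.  Returns the smallest magnitude in
    ``bracket`` whose simulated fraction lies within ``tolerance`` of the
    target.

    ``tolerance`` must exceed twice the binomial standard error of the
    target fraction at ensemble size ``n``; otherwise the estimate cannot
    resolve the target and the call refuses rather than return noise.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    se = math.sqrt(max(target_fraction * (1.0 - target_fraction), 0.0) / n)
    if tolerance <= 2.0 * se:
        raise CalibrationError(
            f"tolerance {tolerance:g} does not exceed 2×binomial SE "
            f"({2 * se:g}) at n={n}; increase n or loosen the tolerance"
        )
    props = props or ParticleProperties()
    base = forces or ForceConfig(overdamped=True)
    lo, hi = bracket
    if not (0.0 <= lo < hi):
        raise ValueError("bracket must satisfy 0 ≤ lo < hi")
    if force_resolution is None:
        force_resolution = (hi - lo) / 4096.0

    def run(force: float) -> float:
        cfg = ForceConfig(
            drag=base.drag,
            gravity=base.gravity,
            g=base.g,
            protrusion_magnitude=force,
            crossing_probability=base.crossing_probability,
            overdamped=base.overdamped,
        )
        res = trace_ensemble(
            geometry, field, props, cfg, n=n, duration=duration, dt=dt,
            seed=seed, fluid=fluid, n_trajectory_samples=0, max_events=0,
        )
        frac = res.extravasated_fraction
        if history is not None:
            history.append((force, frac))
        return frac

    if target_fraction == 0.0:
        return 0.0
    f_lo = run(lo)
    if abs(f_lo - target_fraction) <= tolerance:
        return lo
    f_hi = run(hi)
    if f_hi + tolerance < target_fraction:
        raise CalibrationError(
            f"target fraction {target_fraction:g} unreachable in bracket "
            f"[{lo:g}, {hi:g}] N: end fractions ({f_lo:g}, {f_hi:g})",
            bracket_fractions=(f_lo, f_hi),
        )
    while hi - lo > force_resolution:
        mid = 0.5 * (lo + hi)
        fm = run(mid)
        if fm < target_fraction:
            lo, f_lo = mid, fm
        else:
            hi, f_hi = mid, fm
        if fm == target_fraction:
            hi, f_hi = mid, fm
            break
    if abs(f_hi - target_fraction) > tolerance:
        raise CalibrationError(
            f"bisection converged to force {hi:g} N with fraction {f_hi:g}, "
            f"outside tolerance {tolerance:g} of target {target_fraction:g}",
            bracket_fractions=(f_lo, f_hi),
        )
    return hi
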