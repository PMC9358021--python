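"""Lagrangian tracing of NK-cell-sized spheres in the frozen flow field.

Each cell is a rigid sphere obeying Newton's law with Stokes drag and
buoyancy-corrected gravity,

    d(m_p v_p)/dt = F_d + F_g,
    F_d = 6πμ r_p (u_f − v_p),
    F_g = m_p g (ρ_p − ρ)/ρ_p  (downward),

optionally extended by a chemotactic protrusion force of constant magnitude,
directed along the membrane normal and active only beneath the membrane
footprint — the sensed chemoattractant leaks through the porous insert floor.

The drag relaxation time τ = m_p/(6πμ r_p) ≈ 8.6 µs is far below any
transport timescale, which makes explicit integration hopelessly stiff.  The
integrator therefore uses the exact solution of the linear-drag ODE over
each step (fluid velocity frozen at the step start):

    v(t+Δt) = v_∞ + (v − v_∞) e^(−Δt/τ),   v_∞ = u_f + (F_g + F_prot)/(6πμ r_p),

with the position advanced by the analytic integral of that expression.  In
``overdamped`` mode the velocity is set to v_∞ directly (the τ → 0 limit);
the two agree to well under a nanometre whenever Δt ≫ τ.

Walls are elastic: a particle meeting a wall rebounds specularly with its
speed (hence momentum magnitude) preserved exactly.  A particle leaving
through the outlet re-enters at the inlet after a plug-flow transit delay
through the unmeshed pump-loop volume.  Particles are one-way coupled: they
feel the fluid, the fluid does not feel them.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
import hashlib
import math

import numpy as np

from .flow import FlowField, FluidProperties
from .geometry import DeviceGeometry

__all__ = [
    "ParticleProperties",
    "ParticleState",
    "ForceConfig",
    "EnsembleResult",
    "relaxation_time",
    "drag_force",
    "gravity_force",
    "advance_particle",
    "reflect_at_wall",
    "handle_membrane_contact",
    "seed_particles",
    "trace_ensemble",
]

CIRCULATING = "circulating"
EXTRAVASATED = "extravasated"
RECIRCULATING = "recirculating"

_EPS = 1.0e-12  # wall clearance after a rebound, m
_G_DEFAULT = 9.81


@dataclass(frozen=True)
class ParticleProperties:
    """NK-cell-as-sphere constants: radius 6 µm, density 1080 kg/m³."""

    radius: float = 6.0e-6  # m
    density: float = 1080.0  # kg/m³

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.density <= 0:
            raise ValueError("particle radius and density must be positive")

    @property
    def mass(self) -> float:
        """Sphere mass (4/3)π r_p³ ρ_p, kg."""
        return (4.0 / 3.0) * math.pi * self.radius**3 * self.density


@dataclass
class ParticleState:
    position: np.ndarray  # (2,) m — (x, z)
    velocity: np.ndarray  # (2,) m/s
    time: float = 0.0
    status: str = CIRCULATING
    pass_count: int = 0
    rng_id: int = 0


@dataclass
class ForceConfig:
    """Which forces act on the particles, and the membrane-crossing rule.

    A membrane contact leads to extravasation only when the protrusion force
    is switched on, the net membrane-normal force is upward, and a Bernoulli
    draw with ``crossing_probability`` succeeds; otherwise the membrane is
    just another elastic wall.  With ``protrusion_magnitude = 0`` no particle
    can ever cross — fluid motion alone produces no extravasation.
    """

    drag: bool = True
    gravity: bool = True
    g: float = _G_DEFAULT  # m/s²
    protrusion_magnitude: float = 0.0  # N, along +membrane-normal
    crossing_probability: float = 1.0
    overdamped: bool = False

    def __post_init__(self) -> None:
        if self.protrusion_magnitude < 0:
            raise ValueError("protrusion_magnitude must be non-negative")
        if not 0.0 <= self.crossing_probability <= 1.0:
            raise ValueError("crossing_probability must lie in [0, 1]")


def relaxation_time(props: ParticleProperties, fluid: FluidProperties) -> float:
    """Momentum relaxation time τ = m_p/(6πμ r_p) = 2 ρ_p r_p²/(9μ), s."""
    return 2.0 * props.density * props.radius**2 / (9.0 * fluid.viscosity)


def drag_force(v_p, u_f, props: ParticleProperties, fluid: FluidProperties):
    """Stokes drag 6πμ r_p (u_f − v_p), N."""
    v_p = np.asarray(v_p, dtype=float)
    u_f = np.asarray(u_f, dtype=float)
    if not (np.all(np.isfinite(v_p)) and np.all(np.isfinite(u_f))):
        raise ValueError("velocities must be finite")
    return 6.0 * math.pi * fluid.viscosity * props.radius * (u_f - v_p)


def gravity_force(
    props: ParticleProperties,
    fluid: FluidProperties,
    g_direction=(0.0, -1.0),
    g: float = _G_DEFAULT,
):
    """Buoyant weight m_p g (ρ_p − ρ)/ρ_p along the gravity direction, N."""
    mag = props.mass * g * (props.density - fluid.density) / props.density
    return mag * np.asarray(g_direction, dtype=float)


def settling_speed(props: ParticleProperties, fluid: FluidProperties, g: float = _G_DEFAULT) -> float:
    """Stokes terminal settling speed 2 r_p² (ρ_p − ρ) g / (9μ), m/s."""
    return (
        2.0
        * props.radius**2
        * (props.density - fluid.density)
        * g
        / (9.0 * fluid.viscosity)
    )


def _mobility(props: ParticleProperties, fluid: FluidProperties) -> float:
    """Inverse drag coefficient 1/(6πμ r_p), (m/s)/N."""
    return 1.0 / (6.0 * math.pi * fluid.viscosity * props.radius)


def advance_particle(
    state: ParticleState,
    field: FlowField,
    forces: ForceConfig,
    props: ParticleProperties,
    dt: float,
    fluid: FluidProperties | None = None,
) -> ParticleState:
    """Free-flight step of the drag/gravity ODE (no wall handling).

    The fluid velocity is frozen at the step's starting position; the
    velocity follows the exact exponential solution and the position its
    analytic time integral.  Collisions with walls are resolved separately.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    fluid = fluid or field.fluid
    x, z = state.position
    uf = np.array(field.velocity_at(x, z), dtype=float)
    v_inf = uf.copy()
    mob = _mobility(props, fluid)
    if forces.gravity:
        v_inf += mob * gravity_force(props, fluid, g=forces.g)
    if forces.protrusion_magnitude > 0 and _under_membrane(field.grid.geometry, x):
        v_inf[1] += mob * forces.protrusion_magnitude
    if not forces.drag:
        # ballistic: constant body-force acceleration, no fluid coupling
        acc = (
            gravity_force(props, fluid, g=forces.g) / props.mass
            if forces.gravity
            else np.zeros(2)
        )
        new_v = state.velocity + acc * dt
        new_x = state.position + state.velocity * dt + 0.5 * acc * dt**2
    elif forces.overdamped:
        new_v = v_inf
        new_x = state.position + v_inf * dt
    else:
        tau = relaxation_time(props, fluid)
        decay = math.exp(-dt / tau)
        dv = state.velocity - v_inf
        new_v = v_inf + dv * decay
        new_x = state.position + v_inf * dt + dv * tau * (1.0 - decay)
    return replace(state, position=new_x, velocity=new_v, time=state.time + dt)


def _under_membrane(geometry: DeviceGeometry, x) -> np.ndarray | bool:
    if geometry.mode != "planar_chamber":
        return np.zeros(np.shape(x), dtype=bool) if np.ndim(x) else False
    mx0, mx1 = geometry.membrane_x_extent
    return (np.asarray(x) >= mx0) & (np.asarray(x) <= mx1)


def reflect_at_wall(state: ParticleState, wall_normal) -> ParticleState:
    """Specular elastic rebound: v → v − 2(v·n)n; speed preserved exactly."""
    n = np.asarray(wall_normal, dtype=float)
    n = n / np.linalg.norm(n)
    v = state.velocity - 2.0 * (state.velocity @ n) * n
    return replace(state, velocity=v)


def net_membrane_normal_force(
    forces: ForceConfig,
    props: ParticleProperties | None = None,
    fluid: FluidProperties | None = None,
) -> float:
    """Protrusion minus buoyant weight along the membrane normal, N."""
    props = props or ParticleProperties()
    fluid = fluid or FluidProperties()
    f = forces.protrusion_magnitude
    if forces.gravity:
        f -= props.mass * forces.g * (props.density - fluid.density) / props.density
    return f


def handle_membrane_contact(
    state: ParticleState,
    forces: ForceConfig,
    rng: np.random.Generator,
    props: ParticleProperties | None = None,
    fluid: FluidProperties | None = None,
) -> ParticleState:
    """Resolve a contact with the membrane footprint on the chamber ceiling.

    Crossing requires an active protrusion force, a net upward force, and a
    successful Bernoulli draw; anything else is an elastic rebound.
    """
    can_cross = (
        forces.protrusion_magnitude > 0
        and net_membrane_normal_force(forces, props, fluid) > 0
    )
    if can_cross:
        p = forces.crossing_probability
        if p >= 1.0 or (p > 0.0 and rng.random() < p):
            return replace(state, status=EXTRAVASATED, velocity=state.velocity * 0.0)
    return reflect_at_wall(state, (0.0, 1.0))


def seed_particles(
    n: int,
    geometry: DeviceGeometry,
    field: FlowField | None,
    rng_seed: int,
) -> list[ParticleState]:
    """Seed ``n`` particles uniformly over the fluid section.

    Positions are drawn by rejection sampling from each particle's own
    substream (spawned from ``rng_seed``), so the first k particles of a run
    are identical whatever the ensemble size.  Initial velocity is the local
    fluid velocity (no slip at release).
    """
    if n < 1:
        raise ValueError("need at least one particle")
    gens = _particle_generators(rng_seed, n)
    rects = geometry.rectangles()
    x0 = min(r.x0 for r in rects)
    x1 = max(r.x1 for r in rects)
    z0 = min(r.z0 for r in rects)
    z1 = max(r.z1 for r in rects)
    states = []
    for pid, g in enumerate(gens):
        while True:
            px = g.uniform(x0, x1)
            pz = g.uniform(z0, z1)
            if bool(geometry.inside(px, pz, tol=-1e-9)):
                break
        vel = np.zeros(2)
        if field is not None:
            vel = np.array(field.velocity_at(px, pz), dtype=float)
        states.append(
            ParticleState(
                position=np.array([px, pz]),
                velocity=vel,
                time=0.0,
                status=CIRCULATING,
                pass_count=0,
                rng_id=pid,
            )
        )
    return states


def _particle_generators(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class EnsembleResult:
    """Outcome of a traced ensemble: final states, events, and counters."""

    n: int
    duration: float
    dt: float
    seed: int
    positions: np.ndarray  # (n, 2)
    velocities: np.ndarray  # (n, 2)
    statuses: np.ndarray  # (n,) of {0 circulating, 1 extravasated, 2 recirculating}
    pass_counts: np.ndarray  # (n,)
    crossing_times: np.ndarray  # (n,) NaN where not extravasated
    first_floor_contact: np.ndarray  # (n,) NaN where never hit the floor
    counts: dict
    events: list  # [(particle_id, time_s, event, x_m, z_m)], capped
    events_truncated: bool
    trajectories: dict  # particle_id -> array (t, x, z, vx, vz)
    height_series: np.ndarray  # (m, 2): time, mean height of in-device particles
    geometry_fingerprint: str
    config_fingerprint: str

    @property
    def n_extravasated(self) -> int:
        return int((self.statuses == 1).sum())

    @property
    def extravasated_fraction(self) -> float:
        return self.n_extravasated / self.n

    def status_names(self) -> np.ndarray:
        names = np.array([CIRCULATING, EXTRAVASATED, RECIRCULATING])
        return names[self.statuses]


def _fingerprint(*parts) -> str:
    blob = "|".join(repr(p) for p in parts).encode()
    return hashlib.sha1(blob).hexdigest()[:16]


def geometry_fingerprint(geometry: DeviceGeometry) -> str:
    return _fingerprint(
        geometry.mode,
        geometry.channel_diameter,
        geometry.channel_length,
        geometry.chamber_diameter,
        geometry.chamber_height,
        geometry.membrane_diameter,
        geometry.circuit_volume,
    )


def trace_ensemble(
    geometry: DeviceGeometry,
    field: FlowField,
    props: ParticleProperties,
    forces: ForceConfig,
    n: int,
    duration: float,
    dt: float,
    seed: int,
    recirculation: bool = True,
    fluid: FluidProperties | None = None,
    n_trajectory_samples: int = 10,
    max_events: int = 200_000,
) -> EnsembleResult:
    """Advance ``n`` particles through ``duration`` seconds of device time.

    Particles advance with the exponential drag integrator, rebound
    elastically off walls, may cross the membrane under the crossing rule,
    and re-enter at the inlet after leaving through the outlet (plug-flow
    delay through the unmeshed circuit volume).  Fully reproducible for a
    given seed; particle substreams make the first k particles independent
    of the ensemble size.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    fluid = fluid or field.fluid
    tube = geometry.mode == "axisymmetric_tube"

    states = seed_particles(n, geometry, field, seed)
    gens = _particle_generators(seed + 1, n)  # event draws, separate stream family
    pos = np.array([s.position for s in states])
    vel = np.array([s.velocity for s in states])
    status = np.zeros(n, dtype=np.int8)
    pass_counts = np.zeros(n, dtype=np.int64)
    reentry_time = np.full(n, np.inf)
    crossing_times = np.full(n, np.nan)
    first_floor = np.full(n, np.nan)

    rects = geometry.rectangles()
    lx = geometry.domain_length
    if geometry.mode == "planar_chamber":
        mem_z = geometry.membrane_plane_height
        mx0, mx1 = geometry.membrane_x_extent
    else:
        mem_z, mx0, mx1 = np.inf, 0.0, -1.0
    inlet_z0, inlet_z1 = geometry.inlet_opening

    q = field.flow_rate
    loop_volume = geometry.circuit_volume - geometry.fluid_volume_3d()
    if recirculation and q > 0 and loop_volume > 0:
        transit_delay = loop_volume / q
        outlet_open = True
    else:
        transit_delay = math.inf
        outlet_open = False

    mob = _mobility(props, fluid)
    tau = relaxation_time(props, fluid)
    g_drift = np.zeros(2)
    if forces.gravity:
        g_drift = mob * gravity_force(props, fluid, g=forces.g)
    prot_drift = mob * forces.protrusion_magnitude  # along +z, gated by footprint
    can_cross = (
        forces.protrusion_magnitude > 0
        and net_membrane_normal_force(forces, props, fluid) > 0
    )
    p_cross = forces.crossing_probability

    counts = {"rebounds": 0, "membrane_contacts": 0, "crossings": 0, "recirculations": 0}
    events: list[tuple] = []
    truncated = False

    def log(pid: int, t_ev: float, name: str, x: float, z: float) -> None:
        nonlocal truncated
        if len(events) < max_events:
            events.append((int(pid), float(t_ev), name, float(x), float(z)))
        else:
            truncated = True

    steps = int(round(duration / dt))
    traj_ids = list(range(min(n, n_trajectory_samples)))
    traj_every = max(1, steps // 400) if steps else 1
    traj: dict[int, list] = {pid: [] for pid in traj_ids}
    series_every = max(1, steps // 2000) if steps else 1
    series: list[tuple[float, float]] = []

    decay = math.exp(-dt / tau) if not forces.overdamped else 0.0

    def sample_traj(t_now: float) -> None:
        for pid in traj_ids:
            traj[pid].append((t_now, pos[pid, 0], pos[pid, 1], vel[pid, 0], vel[pid, 1]))

    def sample_series(t_now: float) -> None:
        in_dev = status == 0
        if in_dev.any():
            series.append((t_now, float(pos[in_dev, 1].mean())))

    sample_traj(0.0)
    sample_series(0.0)

    for step in range(steps):
        t = step * dt
        # re-inject recirculating particles whose transit delay has elapsed
        back = np.flatnonzero((status == 2) & (reentry_time <= t))
        for pid in back:
            zr = gens[pid].uniform(inlet_z0 + 1e-9, inlet_z1 - 1e-9)
            pos[pid] = (1e-9, zr)
            uf = field.velocity_at(pos[pid, 0], pos[pid, 1])
            vel[pid] = (uf[0], uf[1])
            status[pid] = 0
            reentry_time[pid] = np.inf

        act_all = np.flatnonzero(status == 0)
        if len(act_all) == 0:
            if (step + 1) % series_every == 0:
                sample_series(t + dt)
            continue

        # fast path: a particle sitting on the floor with a net downward
        # force stays put — the fluid velocity vanishes there by no-slip and
        # the micro-rebound cycle has no net displacement.  Wakes up as soon
        # as the protrusion lift applies (under the membrane footprint).
        xa, za = pos[act_all, 0], pos[act_all, 1]
        resting = (za < 1.0e-9) & (g_drift[1] < 0)
        if prot_drift > 0 and not tube and prot_drift + g_drift[1] > 0:
            resting &= ~((xa >= mx0) & (xa <= mx1))
        vel[act_all[resting]] = 0.0
        # a particle can glide into the resting band without a discrete
        # bounce; entering it counts as reaching the floor
        landed = act_all[resting]
        newly_landed = landed[np.isnan(first_floor[landed])]
        first_floor[newly_landed] = t
        act = act_all[~resting]
        if len(act) == 0:
            if (step + 1) % traj_every == 0:
                sample_traj(t + dt)
            if (step + 1) % series_every == 0:
                sample_series(t + dt)
            continue

        x, z = pos[act, 0], pos[act, 1]
        ufx, ufz = field.velocity_at(x, z)
        v_inf = np.stack([ufx, ufz], axis=1)
        v_inf += g_drift
        if prot_drift > 0 and not tube:
            v_inf[:, 1] += prot_drift * ((x >= mx0) & (x <= mx1))
        if forces.overdamped:
            new_v = v_inf
            disp = v_inf * dt
        else:
            dv = vel[act] - v_inf
            new_v = v_inf + dv * decay
            disp = v_inf * dt + dv * (tau * (1.0 - decay))

        cur = pos[act].copy()
        v = new_v.copy()
        rem = disp.copy()
        frac = np.zeros(len(act))
        done = np.zeros(len(act), dtype=bool)

        for _ in range(16):
            tgt = cur + rem
            ok = np.asarray(geometry.inside(tgt[:, 0], tgt[:, 1], tol=-1e-15))
            fin = ~done & ok
            cur[fin] = tgt[fin]
            done[fin] = True
            work = np.flatnonzero(~done)
            if len(work) == 0:
                break
            cw, rw = cur[work], rem[work]
            m = len(work)
            jj = np.arange(m)
            # containing rectangle of the current position → exit face.  A
            # point on an internal interface lies in two rectangles; take the
            # one that lets the motion travel farthest (largest exit time),
            # which resolves the interface in the direction of travel.
            t_hit = np.full(m, -np.inf)
            axis = np.zeros(m, dtype=np.int8)
            plane = np.zeros(m)
            found = np.zeros(m, dtype=bool)
            for rect in rects:
                inr = rect.contains(cw[:, 0], cw[:, 1], tol=_EPS)
                if not inr.any():
                    continue
                idx = np.flatnonzero(inr)
                t_rect = np.full(len(idx), np.inf)
                ax_rect = np.zeros(len(idx), dtype=np.int8)
                pl_rect = np.zeros(len(idx))
                for ax_, lo, hi in ((0, rect.x0, rect.x1), (1, rect.z0, rect.z1)):
                    r_ax = rw[idx, ax_]
                    bound = np.where(r_ax > 0, hi, lo)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        ta = np.where(r_ax != 0.0, (bound - cw[idx, ax_]) / r_ax, np.inf)
                    ta = np.where(ta < 0, 0.0, ta)
                    closer = ta < t_rect
                    t_rect = np.where(closer, ta, t_rect)
                    ax_rect = np.where(closer, ax_, ax_rect)
                    pl_rect = np.where(closer, bound, pl_rect)
                better = t_rect > t_hit[idx]
                t_hit[idx] = np.where(better, t_rect, t_hit[idx])
                axis[idx] = np.where(better, ax_rect, axis[idx])
                plane[idx] = np.where(better, pl_rect, plane[idx])
                found[idx] = True
            if not found.all():
                bad = int(act[work[np.flatnonzero(~found)[0]]])
                raise RuntimeError(
                    f"particle {bad} left the fluid region at t={t:.6g} s; "
                    "collision resolution failed (no containing rectangle)"
                )
            t_hit = np.minimum(t_hit, 1.0)
            hitp = cw + t_hit[:, None] * rw
            frac[work] += (1.0 - frac[work]) * t_hit
            t_ev = t + dt * frac[work]
            scale = 1.0 - t_hit

            sgn = np.sign(rw[jj, axis])
            beyond = hitp.copy()
            beyond[jj, axis] = plane + sgn * _EPS
            through = np.asarray(geometry.inside(beyond[:, 0], beyond[:, 1], tol=-1e-15))

            m_out = (
                (~through) & (axis == 0) & (sgn > 0) & (np.abs(plane - lx) < 1e-12)
                if outlet_open
                else np.zeros(m, dtype=bool)
            )
            m_mem = (
                (~through)
                & (axis == 1)
                & (sgn > 0)
                & (np.abs(plane - mem_z) < 1e-12)
                & (hitp[:, 0] >= mx0)
                & (hitp[:, 0] <= mx1)
            )
            # membrane-crossing rule: protrusion on ∧ net upward force ∧ Bernoulli
            if can_cross and m_mem.any():
                if p_cross >= 1.0:
                    m_cross = m_mem.copy()
                else:
                    m_cross = np.zeros(m, dtype=bool)
                    if p_cross > 0.0:
                        for j in np.flatnonzero(m_mem):
                            m_cross[j] = gens[act[work[j]]].random() < p_cross
            else:
                m_cross = np.zeros(m, dtype=bool)
            m_reb = ~through & ~m_out & ~m_cross
            counts["membrane_contacts"] += int(m_mem.sum())

            # pass-through of an internal interface between rectangles
            thr = np.flatnonzero(through)
            if len(thr):
                cur[work[thr]] = beyond[thr]
                rem[work[thr]] = scale[thr, None] * rw[thr]

            if m_out.any():
                oj = np.flatnonzero(m_out)
                pids = act[work[oj]]
                counts["recirculations"] += len(oj)
                pass_counts[pids] += 1
                status[pids] = 2
                reentry_time[pids] = t_ev[oj] + transit_delay
                cur[work[oj]] = hitp[oj]
                rem[work[oj]] = 0.0
                done[work[oj]] = True
                for j in oj:
                    log(act[work[j]], t_ev[j], "outlet_recirculation", hitp[j, 0], hitp[j, 1])

            if m_cross.any():
                cj = np.flatnonzero(m_cross)
                pids = act[work[cj]]
                counts["crossings"] += len(cj)
                status[pids] = 1
                crossing_times[pids] = t_ev[cj]
                cur[work[cj]] = hitp[cj]
                v[work[cj]] = 0.0
                rem[work[cj]] = 0.0
                done[work[cj]] = True
                for j in cj:
                    log(act[work[j]], t_ev[j], "crossing", hitp[j, 0], hitp[j, 1])

            if m_reb.any():
                rj = np.flatnonzero(m_reb)
                pids = act[work[rj]]
                counts["rebounds"] += len(rj)
                newc = hitp[rj]
                newc[np.arange(len(rj)), axis[rj]] = plane[rj] - sgn[rj] * _EPS
                cur[work[rj]] = newc
                nr = scale[rj, None] * rw[rj]
                nr[np.arange(len(rj)), axis[rj]] *= -1.0
                rem[work[rj]] = nr
                v[work[rj], axis[rj]] *= -1.0  # specular: flip normal component
                floor_hit = (axis[rj] == 1) & (np.abs(plane[rj]) < 1e-12)
                fh = pids[floor_hit]
                newly = np.isnan(first_floor[fh])
                first_floor[fh[newly]] = t_ev[rj][floor_hit][newly]
                if len(events) < max_events:
                    for j in rj:
                        name = "membrane_contact_rebound" if m_mem[j] else "rebound"
                        log(act[work[j]], t_ev[j], name, hitp[j, 0], hitp[j, 1])
                else:
                    truncated = True
            if np.all(done | (np.abs(rem).max(axis=1) < 1e-18)):
                left = ~done
                cur[left] += rem[left]
                break
        else:
            stuck = np.flatnonzero(~done & (np.abs(rem).max(axis=1) >= 1e-18))
            detail = ", ".join(
                f"particle {act[j]} at ({cur[j, 0]:.9g}, {cur[j, 1]:.9g}) "
                f"rem=({rem[j, 0]:.3g}, {rem[j, 1]:.3g})"
                for j in stuck[:3]
            )
            raise RuntimeError(
                f"collision resolution exceeded its iteration budget at "
                f"t={t:.6g} s ({len(stuck)} unresolved: {detail})"
            )

        pos[act] = cur
        vel[act] = v  # crossing already zeroed v; re-entry overwrites later

        if (step + 1) % traj_every == 0:
            sample_traj(t + dt)
        if (step + 1) % series_every == 0:
            sample_series(t + dt)

    config_fp = _fingerprint(
        geometry_fingerprint(geometry),
        props,
        forces,
        fluid,
        field.flow_rate,
        duration,
        dt,
        n,
        recirculation,
    )
    return EnsembleResult(
        n=n,
        duration=duration,
        dt=dt,
        seed=seed,
        positions=pos,
        velocities=vel,
        statuses=status,
        pass_counts=pass_counts,
        crossing_times=crossing_times,
        first_floor_contact=first_floor,
        counts=counts,
        events=events,
        events_truncated=truncated,
        trajectories={pid: np.array(rows) for pid, rows in traj.items()},
        height_series=np.array(series) if series else np.empty((0, 2)),
        geometry_fingerprint=geometry_fingerprint(geometry),
        config_fingerprint=config_fp,
    )
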