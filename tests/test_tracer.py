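import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oocflow import (
    FluidProperties,
    ForceConfig,
    ParticleProperties,
    ParticleState,
    advance_particle,
    drag_force,
    gravity_force,
    handle_membrane_contact,
    reflect_at_wall,
    relaxation_time,
    seed_particles,
    settling_speed,
    trace_ensemble,
)


class TestForces:
    def test_relaxation_time_default(self, props, fluid):
        assert math.isclose(relaxation_time(props, fluid), 8.64e-6, rel_tol=1e-9)

    def test_relaxation_time_scalings(self, props, fluid):
        big = ParticleProperties(radius=2 * props.radius, density=props.density)
        assert math.isclose(
            relaxation_time(big, fluid), 4 * relaxation_time(props, fluid), rel_tol=1e-12
        )
        thick = FluidProperties(viscosity=2 * fluid.viscosity)
        assert math.isclose(
            relaxation_time(props, thick), relaxation_time(props, fluid) / 2, rel_tol=1e-12
        )

    def test_mass_consistent_with_radius_density(self, props):
        assert math.isclose(
            props.mass, (4 / 3) * math.pi * props.radius**3 * props.density, rel_tol=1e-15
        )

    def test_drag_zero_at_equilibrium(self, props, fluid):
        f = drag_force((1e-3, -2e-3), (1e-3, -2e-3), props, fluid)
        assert np.all(f == 0.0)

    def test_drag_on_stationary_particle(self, props, fluid):
        f = drag_force((0.0, 0.0), (1.273e-2, 0.0), props, fluid)
        assert math.isclose(f[0], 1.44e-9, rel_tol=1e-2)
        assert f[1] == 0.0

    def test_drag_antisymmetry(self, props, fluid):
        a = drag_force((1e-3, 2e-3), (-3e-3, 5e-4), props, fluid)
        b = drag_force((-3e-3, 5e-4), (1e-3, 2e-3), props, fluid)
        assert np.allclose(a, -b, rtol=0, atol=0)

    def test_gravity_magnitude_and_direction(self, props, fluid):
        f = gravity_force(props, fluid)
        assert math.isclose(np.linalg.norm(f), 7.10e-13, rel_tol=1e-2)
        assert f[1] < 0  # away from the membrane (downward)

    def test_neutral_buoyancy(self, props):
        f = gravity_force(props, FluidProperties(density=props.density))
        assert np.all(f == 0.0)

    def test_terminal_settling_speed(self, props, fluid):
        v = settling_speed(props, fluid)
        assert math.isclose(v, 6.28e-6, rel_tol=1e-2)
        fg = np.linalg.norm(gravity_force(props, fluid))
        assert math.isclose(
            v, fg / (6 * math.pi * fluid.viscosity * props.radius), rel_tol=1e-12
        )


class TestAdvanceParticle:
    def test_reaches_terminal_velocity_in_quiescent_fluid(self, still_field, props, fluid):
        st_ = ParticleState(position=np.array([2e-3, 1e-3]), velocity=np.zeros(2))
        st_ = advance_particle(st_, still_field, ForceConfig(), props, dt=1e-3)
        assert math.isclose(abs(st_.velocity[1]), settling_speed(props, fluid), rel_tol=1e-3)

    def test_advects_with_uniform_flow(self, uniform_field, props):
        st_ = ParticleState(
            position=np.array([1e-3, 0.75e-3]), velocity=np.array([1e-3, 0.0])
        )
        out = advance_particle(
            st_, uniform_field, ForceConfig(gravity=False), props, dt=0.1
        )
        assert np.allclose(out.position, [1e-3 + 1e-4, 0.75e-3], rtol=0, atol=1e-15)
        assert np.allclose(out.velocity, [1e-3, 0.0], rtol=0, atol=1e-18)

    def test_overdamped_equivalence_at_large_dt(self, still_field, props, fluid):
        """Full and overdamped integrators agree within 1 nm when dt ≥ 100 τ."""
        tau = relaxation_time(props, fluid)
        dt = 1e-3
        assert dt > 100 * tau
        a = ParticleState(position=np.array([2e-3, 1.2e-3]), velocity=np.zeros(2))
        b = ParticleState(position=np.array([2e-3, 1.2e-3]), velocity=np.zeros(2))
        for _ in range(10_000):  # 10 s of settling
            a = advance_particle(a, still_field, ForceConfig(overdamped=False), props, dt)
            b = advance_particle(b, still_field, ForceConfig(overdamped=True), props, dt)
        assert np.abs(a.position - b.position).max() < 1e-9

    def test_nonpositive_dt_rejected(self, still_field, props):
        st_ = ParticleState(position=np.array([2e-3, 1e-3]), velocity=np.zeros(2))
        with pytest.raises(ValueError):
            advance_particle(st_, still_field, ForceConfig(), props, dt=0.0)


class TestReflection:
    def test_specular_floor_reflection(self):
        st_ = ParticleState(
            position=np.array([1e-3, 0.0]), velocity=np.array([1.0, -1.0])
        )
        out = reflect_at_wall(st_, (0.0, 1.0))
        assert np.allclose(out.velocity, [1.0, 1.0], rtol=0, atol=0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        vx=st.floats(-1e-1, 1e-1, allow_nan=False),
        vz=st.floats(-1e-1, 1e-1, allow_nan=False),
        angle=st.floats(0, 2 * math.pi, allow_nan=False),
    )
    def test_speed_preserved_to_machine_precision(self, vx, vz, angle):
        n = (math.cos(angle), math.sin(angle))
        st_ = ParticleState(position=np.zeros(2), velocity=np.array([vx, vz]))
        out = reflect_at_wall(st_, n)
        assert math.isclose(
            np.linalg.norm(out.velocity),
            np.linalg.norm(st_.velocity),
            rel_tol=1e-12,
            abs_tol=1e-300,
        )


class TestMembraneContact:
    def _state(self):
        return ParticleState(
            position=np.array([8e-3, 1.5e-3]), velocity=np.array([1e-4, 2e-6])
        )

    def test_no_protrusion_always_rebounds(self):
        rng = np.random.default_rng(0)
        out = handle_membrane_contact(self._state(), ForceConfig(), rng)
        assert out.status == "circulating"
        assert out.velocity[1] < 0  # bounced back down

    def test_sufficient_protrusion_crosses(self):
        # 1e-11 N ≫ buoyant weight 7.1e-13 N → net upward force
        rng = np.random.default_rng(0)
        out = handle_membrane_contact(
            self._state(), ForceConfig(protrusion_magnitude=1e-11), rng
        )
        assert out.status == "extravasated"

    def test_subgravity_protrusion_rebounds(self):
        rng = np.random.default_rng(0)
        out = handle_membrane_contact(
            self._state(), ForceConfig(protrusion_magnitude=1e-13), rng
        )
        assert out.status == "circulating"

    def test_zero_probability_behaves_like_wall(self):
        rng = np.random.default_rng(0)
        out = handle_membrane_contact(
            self._state(),
            ForceConfig(protrusion_magnitude=1e-11, crossing_probability=0.0),
            rng,
        )
        assert out.status == "circulating"


class TestSeeding:
    def test_deterministic_given_seed(self, reference_geometry, reference_solution):
        _, field = reference_solution
        a = seed_particles(100, reference_geometry, field, rng_seed=42)
        b = seed_particles(100, reference_geometry, field, rng_seed=42)
        assert all(np.array_equal(x.position, y.position) for x, y in zip(a, b))
        assert all(np.array_equal(x.velocity, y.velocity) for x, y in zip(a, b))

    def test_prefix_stable_under_ensemble_growth(self, reference_geometry, reference_solution):
        _, field = reference_solution
        a = seed_particles(10, reference_geometry, field, rng_seed=7)
        b = seed_particles(50, reference_geometry, field, rng_seed=7)
        assert all(np.array_equal(x.position, y.position) for x, y in zip(a, b[:10]))

    def test_all_positions_inside_fluid(self, reference_geometry, reference_solution):
        _, field = reference_solution
        states = seed_particles(500, reference_geometry, field, rng_seed=3)
        xs = np.array([s.position for s in states])
        assert bool(np.all(reference_geometry.inside(xs[:, 0], xs[:, 1])))

    def test_effector_count_for_target_ratio(self):
        # 10:1 effector:target bookkeeping at the reported tumor load
        n_targets = 3e4
        assert int(10 * n_targets) == 300_000


class TestEnsemble:
    def test_zero_duration_echoes_initial_states(
        self, reference_geometry, reference_solution, props
    ):
        _, field = reference_solution
        res = trace_ensemble(
            reference_geometry, field, props, ForceConfig(), n=20,
            duration=0.0, dt=1e-3, seed=11,
        )
        seeds = seed_particles(20, reference_geometry, field, rng_seed=11)
        assert np.allclose(res.positions, [s.position for s in seeds], rtol=0, atol=0)
        assert res.events == []
        assert res.n_extravasated == 0

    def test_status_partition(self, reference_geometry, reference_solution, props):
        _, field = reference_solution
        res = trace_ensemble(
            reference_geometry, field, props, ForceConfig(overdamped=True),
            n=100, duration=60.0, dt=0.02, seed=5,
        )
        assert ((res.statuses == 0) | (res.statuses == 1) | (res.statuses == 2)).all()
        assert len(res.statuses) == res.n

    def test_recirculation_increments_pass_count(
        self, reference_geometry, reference_solution, props
    ):
        _, field = reference_solution
        res = trace_ensemble(
            reference_geometry, field, props, ForceConfig(overdamped=True),
            n=100, duration=60.0, dt=0.02, seed=5,
        )
        assert res.counts["recirculations"] > 0
        assert res.pass_counts.sum() == res.counts["recirculations"]

    def test_event_times_within_run(self, reference_geometry, reference_solution, props):
        _, field = reference_solution
        res = trace_ensemble(
            reference_geometry, field, props, ForceConfig(overdamped=True),
            n=50, duration=30.0, dt=0.02, seed=9,
        )
        times = [e[1] for e in res.events]
        assert all(0.0 <= t <= 30.0 + 1e-9 for t in times)

    def test_reproducible_given_seed(self, reference_geometry, reference_solution, props):
        _, field = reference_solution
        kw = dict(n=50, duration=30.0, dt=0.02, seed=21)
        r1 = trace_ensemble(
            reference_geometry, field, props, ForceConfig(overdamped=True), **kw
        )
        r2 = trace_ensemble(
            reference_geometry, field, props, ForceConfig(overdamped=True), **kw
        )
        assert np.array_equal(r1.positions, r2.positions)
        assert r1.counts == r2.counts

    def test_particles_never_inside_solid(self, reference_geometry, reference_solution, props):
        """Positions stay within the fluid region to the stated tolerance."""
        _, field = reference_solution
        res = trace_ensemble(
            reference_geometry, field, props, ForceConfig(overdamped=True),
            n=100, duration=120.0, dt=0.02, seed=13,
        )
        live = res.statuses == 0
        assert bool(
            np.all(
                reference_geometry.inside(
                    res.positions[live, 0], res.positions[live, 1], tol=1e-9
                )
            )
        )

    def test_sedimentation_timescale(self, settling_box, still_field, props, fluid):
        """Mean floor-crossing time matches chamber height over settling speed."""
        res = trace_ensemble(
            settling_box, still_field, props, ForceConfig(overdamped=True),
            n=200, duration=260.0, dt=0.01, seed=3,
        )
        t_char = 2.0 * np.nanmean(res.first_floor_contact)
        expected = settling_box.chamber_height / settling_speed(props, fluid)
        assert abs(t_char - expected) / expected < 0.10
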