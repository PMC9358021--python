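import math

import numpy as np
import pytest

from oocflow import (
    FluidProperties,
    build_tube_benchmark,
    flow_metrics,
    poiseuille_profile,
    rasterize,
    solve_steady_flow,
)
from oocflow.geometry import WALL
from tests.conftest import Q_SI


def _midplane_profile(grid, field):
    i = grid.nx // 2
    sel = grid.fluid_mask[i, :]
    u = 0.5 * (field.u[i, :] + field.u[i + 1, :])[sel]
    return grid.z_centers[sel], u


class TestPoiseuilleProfile:
    def test_centerline_peak(self):
        u0 = poiseuille_profile(0.5e-3, Q_SI, 0.0)
        assert math.isclose(u0, 1.273e-2, rel_tol=2e-3)

    def test_no_slip_at_wall(self):
        assert poiseuille_profile(0.5e-3, Q_SI, 0.5e-3) == 0.0

    def test_profile_integrates_to_flow_rate(self):
        R = 0.5e-3
        r = np.linspace(0, R, 20001)
        u = poiseuille_profile(R, Q_SI, r)
        q = np.trapezoid(u * 2 * np.pi * r, r)
        assert math.isclose(q, Q_SI, rel_tol=1e-6)

    def test_outside_radius_rejected(self):
        with pytest.raises(ValueError):
            poiseuille_profile(0.5e-3, Q_SI, 0.6e-3)


@pytest.fixture(scope="module")
def tube_errors(fluid):
    geom = build_tube_benchmark(0.5e-3, 10e-3)
    errs = []
    for h in (50e-6, 25e-6):
        grid = rasterize(geom, h)
        field = solve_steady_flow(grid, fluid, Q_SI)
        zc, u = _midplane_profile(grid, field)
        exact = poiseuille_profile(0.5e-3, Q_SI, zc)
        errs.append(float(np.abs(u - exact).max() / exact.max()))
    return errs


class TestTubeOracle:
    def test_matches_closed_form_within_two_percent(self, tube_errors):
        assert tube_errors[0] < 0.02

    def test_error_improves_under_refinement(self, tube_errors):
        assert tube_errors[1] < tube_errors[0]


class TestBoundaryContract:
    def test_zero_flow_rate_gives_null_field(self, fluid):
        grid = rasterize(build_tube_benchmark(0.5e-3, 5e-3), 50e-6)
        field = solve_steady_flow(grid, fluid, 0.0)
        assert np.abs(field.u).max() == 0.0
        assert np.abs(field.w).max() == 0.0
        assert np.abs(field.p).max() == 0.0

    def test_no_slip_on_wall_faces(self, reference_solution):
        grid, field = reference_solution
        # any u-face touching a non-fluid cell is exactly zero
        F = grid.fluid_mask
        interior = np.zeros_like(field.u, dtype=bool)
        interior[1:-1, :] = F[:-1, :] & F[1:, :]
        interior[0, F[0, :]] = True
        interior[-1, F[-1, :]] = True
        assert np.abs(field.u[~interior]).max() == 0.0
        wall_w = np.ones_like(field.w, dtype=bool)
        wall_w[:, 1:-1] = ~(F[:, :-1] & F[:, 1:])
        assert np.abs(field.w[wall_w]).max() == 0.0

    def test_outlet_pressure_is_null_in_tube(self, fluid):
        # fully developed tube: pressure is exactly linear, so the last
        # column holds half a cell of the gradient and extrapolates to 0
        # on the outlet plane
        grid = rasterize(build_tube_benchmark(0.5e-3, 5e-3), 50e-6)
        field = solve_steady_flow(grid, fluid, Q_SI)
        sel = grid.fluid_mask[-1, :]
        p_last = field.p[-1, sel]
        dp_dx = (field.p[-2, sel] - field.p[-1, sel]) / grid.spacing
        face = p_last - 0.5 * grid.spacing * dp_dx
        assert np.abs(face).max() < 1e-9 * np.abs(field.p).max()

    def test_outlet_pressure_small_in_device(self, reference_solution):
        grid, field = reference_solution
        sel = grid.fluid_mask[-1, :]
        assert np.abs(field.p[-1, sel]).max() < 0.01 * np.abs(field.p).max()

    def test_membrane_is_impermeable_no_slip_wall(self, reference_solution, reference_geometry):
        grid, field = reference_solution
        k_ceiling = int(round(reference_geometry.membrane_plane_height / grid.spacing))
        mx0, mx1 = reference_geometry.membrane_x_extent
        cols = (grid.x_centers >= mx0) & (grid.x_centers <= mx1)
        assert np.abs(field.w[cols, k_ceiling]).max() == 0.0


class TestConservationAndLinearity:
    def test_divergence_free_in_every_fluid_cell(self, reference_solution):
        _, field = reference_solution
        assert field.max_divergence_residual() < 1e-10

    def test_inlet_outlet_flux_agree(self, reference_solution, fluid):
        grid, field = reference_solution
        m = flow_metrics(field, grid, fluid)
        assert m.flux_mismatch() < 0.005

    def test_doubling_flow_rate_doubles_velocities(self, reference_solution, fluid):
        grid, f1 = reference_solution
        f2 = solve_steady_flow(grid, fluid, 2 * Q_SI)
        scale = np.abs(f1.u).max()
        assert np.abs(f2.u - 2 * f1.u).max() / scale < 0.01
        assert np.abs(f2.w - 2 * f1.w).max() / scale < 0.01


class TestMetrics:
    def test_channel_reynolds_number(self, fluid):
        geom = build_tube_benchmark(0.5e-3, 5e-3)
        grid = rasterize(geom, 50e-6)
        field = solve_steady_flow(grid, fluid, Q_SI)
        m = flow_metrics(field, grid, fluid)
        assert math.isclose(m.reynolds, 6.37, rel_tol=0.01)
        assert m.laminar

    def test_unconverged_field_rejected(self, reference_solution, fluid):
        grid, field = reference_solution
        from dataclasses import replace

        bad = replace(field, converged=False)
        with pytest.raises(ValueError):
            flow_metrics(bad, grid, fluid)

    def test_inertial_correction_small_at_device_reynolds(self, reference_solution, fluid):
        """At Re ≈ 6 the convective term shifts the peak speed by well under 5%."""
        grid, stokes = reference_solution
        ns = solve_steady_flow(
            grid, fluid, Q_SI, include_inertia=True, tolerance=1e-5, max_iterations=120
        )
        assert abs(ns.max_speed() - stokes.max_speed()) / stokes.max_speed() < 0.05
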