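import math

import numpy as np
import pytest

from oocflow import build_reference_device, build_tube_benchmark, rasterize
from oocflow.geometry import FLUID, INLET, MEMBRANE, OUTLET, SOLID, WALL, DeviceGeometry


class TestReferenceDevice:
    def test_circuit_volume_is_chamber_load(self):
        geom = build_reference_device()
        assert geom.circuit_volume == 1.5e-6  # 1.5 ml per chamber

    def test_membrane_is_standard_24well_insert(self):
        geom = build_reference_device()
        assert geom.membrane_diameter == 6.5e-3
        assert geom.membrane_diameter <= geom.chamber_diameter

    def test_gravity_opposes_membrane_normal(self):
        geom = build_reference_device()
        assert math.isclose(
            float(geom.gravity_direction @ geom.membrane_normal), -1.0
        )

    def test_membrane_plane_is_chamber_ceiling(self):
        geom = build_reference_device()
        assert geom.membrane_plane_height == geom.chamber_height

    def test_unmeshed_loop_volume_positive(self):
        geom = build_reference_device()
        assert 0 < geom.fluid_volume_3d() < geom.circuit_volume


class TestTubeBenchmark:
    def test_constructor_echo(self):
        geom = build_tube_benchmark(0.5e-3, 10e-3)
        assert geom.mode == "axisymmetric_tube"
        assert geom.channel_diameter == 1.0e-3
        assert geom.channel_length == 10e-3

    def test_cross_section_area(self):
        geom = build_tube_benchmark(0.5e-3, 10e-3)
        area = geom.fluid_volume_3d() / geom.channel_length
        assert math.isclose(area, math.pi * (0.5e-3) ** 2, rel_tol=1e-12)
        assert math.isclose(area, 7.854e-7, rel_tol=1e-3)

    @pytest.mark.parametrize("radius,length", [(0.5e-3, 0.0), (0.0, 1e-2), (-1e-3, 1e-2)])
    def test_degenerate_dimensions_rejected(self, radius, length):
        with pytest.raises(ValueError):
            build_tube_benchmark(radius, length)


class TestRasterize:
    def test_channel_resolved_across_diameter(self):
        grid = rasterize(build_tube_benchmark(0.5e-3, 10e-3), 50e-6)
        # 1 mm diameter at 50 µm → 10 fluid cells across the radius
        assert grid.fluid_mask[grid.nx // 2, :].sum() == 10

    def test_fluid_volume_matches_analytic(self, reference_geometry):
        grid = rasterize(reference_geometry, 50e-6)
        analytic = reference_geometry.section_area()
        assert abs(grid.fluid_volume() - analytic) / analytic < 0.05

    def test_tube_volume_exact_by_revolution(self):
        geom = build_tube_benchmark(0.5e-3, 10e-3)
        grid = rasterize(geom, 50e-6)
        assert math.isclose(grid.fluid_volume(), geom.fluid_volume_3d(), rel_tol=1e-9)

    def test_volume_error_shrinks_under_refinement(self, reference_geometry):
        analytic = reference_geometry.section_area()
        errs = [
            abs(rasterize(reference_geometry, h).fluid_volume() - analytic) / analytic
            for h in (100e-6, 50e-6)
        ]
        assert errs[1] <= errs[0]

    def test_too_coarse_spacing_rejected_naming_feature(self, reference_geometry):
        with pytest.raises(ValueError, match="channel"):
            rasterize(reference_geometry, reference_geometry.channel_diameter)

    def test_labels_partition_and_boundary_cells_exist(self, reference_geometry):
        grid = rasterize(reference_geometry, 50e-6)
        assert set(np.unique(grid.labels)) <= {FLUID, SOLID, WALL, INLET, OUTLET, MEMBRANE}
        assert (grid.labels == INLET).sum() >= 1
        assert (grid.labels == OUTLET).sum() >= 1
        assert (grid.labels == MEMBRANE).sum() >= 1

    def test_membrane_cells_on_ceiling_within_footprint(self, reference_geometry):
        grid = rasterize(reference_geometry, 50e-6)
        ii, kk = np.nonzero(grid.labels == MEMBRANE)
        # all membrane cells in the single row right above the chamber ceiling
        k_ceiling = int(round(reference_geometry.membrane_plane_height / grid.spacing))
        assert np.all(kk == k_ceiling)
        mx0, mx1 = reference_geometry.membrane_x_extent
        xc = grid.x_centers[ii]
        assert xc.min() >= mx0 and xc.max() <= mx1

    def test_fluid_region_connected_inlet_to_outlet(self, reference_geometry):
        grid = rasterize(reference_geometry, 100e-6)
        fluid = grid.fluid_mask
        seen = np.zeros_like(fluid)
        stack = [(0, k) for k in np.flatnonzero(fluid[0, :])]
        for s in stack:
            seen[s] = True
        while stack:
            i, k = stack.pop()
            for di, dk in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                a, b = i + di, k + dk
                if 0 <= a < grid.nx and 0 <= b < grid.nz and fluid[a, b] and not seen[a, b]:
                    seen[a, b] = True
                    stack.append((a, b))
        assert seen[-1, fluid[-1, :]].all()


class TestInvariants:
    def test_gravity_direction_must_be_unit(self):
        with pytest.raises(ValueError):
            DeviceGeometry(
                mode="planar_chamber",
                channel_diameter=1e-3,
                channel_length=2e-3,
                chamber_diameter=16e-3,
                chamber_height=1.5e-3,
                membrane_diameter=6.5e-3,
                gravity_direction=np.array([0.0, -2.0]),
            )

    def test_membrane_wider_than_chamber_rejected(self):
        with pytest.raises(ValueError):
            DeviceGeometry(
                mode="planar_chamber",
                channel_diameter=1e-3,
                channel_length=2e-3,
                chamber_diameter=6e-3,
                chamber_height=1.5e-3,
                membrane_diameter=16e-3,
            )
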