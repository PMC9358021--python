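import numpy as np
import pytest

from oocflow import (
    DeviceGeometry,
    FluidProperties,
    FlowField,
    ParticleProperties,
    build_reference_device,
    rasterize,
    solve_steady_flow,
)

# experimental perfusion rate: 0.3 ml/min
Q_SI = 0.3e-6 / 60.0


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def props():
    return ParticleProperties()


@pytest.fixture(scope="session")
def reference_geometry():
    return build_reference_device()


@pytest.fixture(scope="session")
def reference_solution(reference_geometry, fluid):
    """Reference device solved at the working 50 µm resolution (reused widely)."""
    grid = rasterize(reference_geometry, 50e-6)
    field = solve_steady_flow(grid, fluid, Q_SI)
    return grid, field


@pytest.fixture(scope="session")
def settling_box():
    """Uniform 1.5 mm-tall box (no internal steps): the quiescent settling case."""
    return DeviceGeometry(
        mode="planar_chamber",
        channel_diameter=1.5e-3,
        channel_length=1.0e-3,
        chamber_diameter=5.0e-3,
        chamber_height=1.5e-3,
        membrane_diameter=1.0e-3,
    )


@pytest.fixture(scope="session")
def still_field(settling_box):
    grid = rasterize(settling_box, 150e-6)
    return FlowField.uniform(grid, (0.0, 0.0))


@pytest.fixture(scope="session")
def uniform_field(settling_box):
    grid = rasterize(settling_box, 150e-6)
    return FlowField.uniform(grid, (1.0e-3, 0.0))
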