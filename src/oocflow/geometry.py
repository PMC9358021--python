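"""Device geometry: perfusion channel(s), chamber, membrane plane, and rasterization.

The simulated device is a transwell-style organ-on-chip: a perfused fluid
chamber whose ceiling carries the porous membrane of a culture insert.
Circulating cells move with the perfusion flow beneath the membrane;
"extravasation" is the crossing of that membrane into the insert above.

Two geometric modes are supported, both resolved on structured grids:

* ``axisymmetric_tube`` — a straight circular tube in (x, r) coordinates,
  used as a closed-form validation case (Poiseuille flow).
* ``planar_chamber`` — a 2-D longitudinal section (x, z) of the device with
  unit depth: an inlet channel, the wide chamber with the membrane set into
  its ceiling, and an outlet channel.  z = 0 is the chamber floor; the
  membrane normal is +z and gravity points along −z.

The fluid region is a union of axis-aligned rectangles, which keeps both
rasterization and particle-wall collision tests exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

# cell classification codes
FLUID = 0
SOLID = 1
WALL = 2  # solid cell face-adjacent to fluid
INLET = 3  # fluid cell in the inlet column
OUTLET = 4  # fluid cell in the outlet column
MEMBRANE = 5  # wall cell on the chamber ceiling, inside the membrane footprint

_FLUID_LIKE = (FLUID, INLET, OUTLET)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle [x0, x1] × [z0, z1] (z is radius in tube mode)."""

    x0: float
    x1: float
    z0: float
    z1: float

    def contains(self, x, z, tol: float = 0.0):
        return (
            (x >= self.x0 - tol)
            & (x <= self.x1 + tol)
            & (z >= self.z0 - tol)
            & (z <= self.z1 + tol)
        )


@dataclass
class DeviceGeometry:
    """Parameterized layout of the chip, SI units throughout.

    ``membrane_plane_height`` equals the chamber ceiling: the membrane is the
    floor of the culture insert sitting on top of the fluid compartment, so a
    cell crossing it leaves the flow circuit upward, against gravity.
    """

    mode: str  # "axisymmetric_tube" | "planar_chamber"
    channel_diameter: float
    channel_length: float
    chamber_diameter: float = 0.0
    chamber_height: float = 0.0
    membrane_diameter: float = 0.0
    circuit_volume: float = 1.5e-6
    gravity_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, -1.0])
    )

    def __post_init__(self) -> None:
        if self.mode not in ("axisymmetric_tube", "planar_chamber"):
            raise ValueError(f"unknown geometry mode {self.mode!r}")
        if self.channel_diameter <= 0 or self.channel_length <= 0:
            raise ValueError("channel dimensions must be strictly positive")
        if self.mode == "planar_chamber":
            for name in ("chamber_diameter", "chamber_height", "membrane_diameter"):
                if getattr(self, name) <= 0:
                    raise ValueError(f"{name} must be strictly positive")
            if self.membrane_diameter > self.chamber_diameter:
                raise ValueError("membrane_diameter must not exceed chamber_diameter")
        if self.circuit_volume <= 0:
            raise ValueError("circuit_volume must be strictly positive")
        g = np.asarray(self.gravity_direction, dtype=float)
        if not math.isclose(float(np.linalg.norm(g)), 1.0, rel_tol=1e-9):
            raise ValueError("gravity_direction must be a unit vector")
        if self.mode == "planar_chamber" and g @ self.membrane_normal >= 0:
            raise ValueError(
                "gravity must have a negative component along the membrane "
                "normal (the membrane is above the flow compartment)"
            )
        self.gravity_direction = g

    # ---- derived layout ---------------------------------------------------

    @property
    def membrane_normal(self) -> np.ndarray:
        return np.array([0.0, 1.0])

    @property
    def membrane_plane_height(self) -> float:
        """Chamber ceiling height (the membrane plane), m."""
        if self.mode != "planar_chamber":
            raise ValueError("tube geometries have no membrane")
        return self.chamber_height

    @property
    def domain_length(self) -> float:
        if self.mode == "axisymmetric_tube":
            return self.channel_length
        return 2.0 * self.channel_length + self.chamber_diameter

    @property
    def membrane_x_extent(self) -> tuple[float, float]:
        """Membrane footprint along x (centered over the chamber), m."""
        xc = self.channel_length + 0.5 * self.chamber_diameter
        return (xc - 0.5 * self.membrane_diameter, xc + 0.5 * self.membrane_diameter)

    def rectangles(self) -> list[Rect]:
        """Fluid region as a union of rectangles (x, z) / (x, r)."""
        if self.mode == "axisymmetric_tube":
            return [Rect(0.0, self.channel_length, 0.0, 0.5 * self.channel_diameter)]
        lc, d, hc = self.channel_length, self.channel_diameter, self.chamber_height
        dc = self.chamber_diameter
        return [
            Rect(0.0, lc, 0.0, d),  # inlet channel (flush with floor)
            Rect(lc, lc + dc, 0.0, hc),  # chamber
            Rect(lc + dc, 2 * lc + dc, 0.0, d),  # outlet channel
        ]

    def inside(self, x, z, tol: float = 0.0):
        """Vectorized membership test for points in the fluid region."""
        x = np.asarray(x, dtype=float)
        z = np.asarray(z, dtype=float)
        out = np.zeros(np.broadcast(x, z).shape, dtype=bool)
        for r in self.rectangles():
            out |= r.contains(x, z, tol)
        return out

    @property
    def inlet_opening(self) -> tuple[float, float]:
        """(z_lo, z_hi) of the inlet cross-section at x = 0."""
        r = self.rectangles()[0]
        return (r.z0, r.z1)

    def section_area(self) -> float:
        """Analytic area of the 2-D fluid section, m² (per-unit-depth measure)."""
        return sum((r.x1 - r.x0) * (r.z1 - r.z0) for r in self.rectangles())

    def fluid_volume_3d(self) -> float:
        """True 3-D fluid volume of the meshed part of the device, m³.

        Tube mode: volume of revolution.  Planar mode: the physical device the
        section stands for — circular channels plus a cylindrical chamber.
        Used for the recirculation transit delay through the unmeshed loop.
        """
        if self.mode == "axisymmetric_tube":
            return math.pi * (0.5 * self.channel_diameter) ** 2 * self.channel_length
        v_channels = (
            2.0
            * math.pi
            * (0.5 * self.channel_diameter) ** 2
            * self.channel_length
        )
        v_chamber = (
            math.pi * (0.5 * self.chamber_diameter) ** 2 * self.chamber_height
        )
        return v_channels + v_chamber


def build_reference_device(
    channel_diameter: float = 1.0e-3,
    channel_length: float = 2.0e-3,
    chamber_diameter: float = 16.0e-3,
    chamber_height: float = 1.5e-3,
    membrane_diameter: float = 6.5e-3,
    circuit_volume: float = 1.5e-6,
) -> DeviceGeometry:
    """Reference transwell-chip geometry.

    The chamber hosts a standard 24-well plate insert (membrane Ø 6.5 mm) and
    is fed by Ø 1.0 mm channels; the circulating circuit holds 1.5 ml, of
    which only the chamber and short channel stubs are meshed — the rest is
    the pump loop, represented by a plug-flow transit delay.  The commercial
    device's internal drawings are not public, so these dimensions are a
    documented reconstruction and every one of them is overridable.
    """
    return DeviceGeometry(
        mode="planar_chamber",
        channel_diameter=channel_diameter,
        channel_length=channel_length,
        chamber_diameter=chamber_diameter,
        chamber_height=chamber_height,
        membrane_diameter=membrane_diameter,
        circuit_volume=circuit_volume,
    )


def build_tube_benchmark(radius: float, length: float) -> DeviceGeometry:
    """Straight circular tube (axisymmetric), the Poiseuille validation case."""
    if radius <= 0 or length <= 0:
        raise ValueError("tube radius and length must be strictly positive")
    return DeviceGeometry(
        mode="axisymmetric_tube",
        channel_diameter=2.0 * radius,
        channel_length=length,
        circuit_volume=1.5e-6,
    )


@dataclass
class StructuredGrid:
    """Uniform structured grid with a cell-classification mask.

    Axis 0 is x (streamwise), axis 1 is z (height; radius in tube mode).
    Cell (i, k) spans [i·h, (i+1)·h] × [k·h, (k+1)·h].
    """

    geometry: DeviceGeometry
    spacing: float
    labels: np.ndarray  # (nx, nz) int8

    @property
    def nx(self) -> int:
        return self.labels.shape[0]

    @property
    def nz(self) -> int:
        return self.labels.shape[1]

    @property
    def fluid_mask(self) -> np.ndarray:
        return np.isin(self.labels, _FLUID_LIKE)

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.spacing

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.spacing

    def cell_volumes(self) -> np.ndarray:
        """Per-cell measure: area (planar, unit depth) or revolved volume (tube)."""
        h = self.spacing
        if self.geometry.mode == "axisymmetric_tube":
            r = self.z_centers  # z axis is the radius
            return np.broadcast_to(2.0 * np.pi * r * h * h, self.labels.shape).copy()
        return np.full(self.labels.shape, h * h)

    def fluid_volume(self) -> float:
        return float(self.cell_volumes()[self.fluid_mask].sum())


def rasterize(geometry: DeviceGeometry, spacing: float) -> StructuredGrid:
    """Rasterize the fluid region onto a uniform grid by cell-center membership.

    The spacing must resolve the narrowest passage (at least 8 cells across
    the channel diameter), otherwise the velocity profile in the channel is
    unusable.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing > geometry.channel_diameter / 8.0:
        raise ValueError(
            "grid spacing too coarse: the narrowest feature is the channel "
            f"(diameter {geometry.channel_diameter:g} m); need spacing ≤ "
            f"{geometry.channel_diameter / 8.0:g} m"
        )
    lx = geometry.domain_length
    if geometry.mode == "axisymmetric_tube":
        ztop = 0.5 * geometry.channel_diameter
    else:
        ztop = max(geometry.chamber_height, geometry.channel_diameter)
    nx = int(round(lx / spacing))
    # one extra row above the ceiling so membrane/wall cells exist in the mask
    nz = int(round(ztop / spacing)) + 1

    xc = (np.arange(nx) + 0.5) * spacing
    zc = (np.arange(nz) + 0.5) * spacing
    X, Z = np.meshgrid(xc, zc, indexing="ij")
    fluid = geometry.inside(X, Z)

    labels = np.where(fluid, FLUID, SOLID).astype(np.int8)

    # solid cells face-adjacent to fluid become walls
    solid = ~fluid
    adj = np.zeros_like(fluid)
    adj[1:, :] |= fluid[:-1, :]
    adj[:-1, :] |= fluid[1:, :]
    adj[:, 1:] |= fluid[:, :-1]
    adj[:, :-1] |= fluid[:, 1:]
    labels[solid & adj] = WALL

    # inlet / outlet fluid columns at the domain ends
    labels[0, fluid[0, :]] = INLET
    labels[-1, fluid[-1, :]] = OUTLET

    if geometry.mode == "planar_chamber":
        mx0, mx1 = geometry.membrane_x_extent
        ceiling = geometry.membrane_plane_height
        k_above = int(round(ceiling / spacing))  # first cell row above ceiling
        if k_above < nz:
            sel = (xc >= mx0) & (xc <= mx1) & (labels[:, k_above] == WALL)
            labels[sel, k_above] = MEMBRANE

    grid = StructuredGrid(geometry=geometry, spacing=spacing, labels=labels)

    analytic = (
        geometry.fluid_volume_3d()
        if geometry.mode == "axisymmetric_tube"
        else geometry.section_area()
    )
    rel = abs(grid.fluid_volume() - analytic) / analytic
    if rel > 0.05:
        raise ValueError(
            f"rasterized fluid volume off by {rel:.1%} from analytic; refine spacing"
        )
    return grid
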