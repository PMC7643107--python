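"""Channel geometry, fluid description, and flow numbers.

Velocity convention: ``U`` is the cross-section mean velocity ``Q/(w*h)``.
The Dean-velocity correlation ``U_D = 1.8e-4 * De**1.63`` is dimensional and
returns m/s for dimensionless De.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DomainError, InvalidGeometryError

#: coefficient (m/s) and exponent of the empirical Dean-velocity correlation
DEAN_VELOCITY_COEFF = 1.8e-4
DEAN_VELOCITY_EXPONENT = 1.63


@dataclass(frozen=True)
class RectChannel:
    """Spiral channel with rectangular cross-section.

    Parameters
    ----------
    width, height : float
        Cross-section dimensions in metres.
    spiral_radius : float
        Representative radius of curvature of the channel path, metres.
    n_loops, loop_spacing : int, float
        Spiral layout (informational; not used by the flow formulas).
    n_outlets, outlet_width : int, float
        The channel width is evenly split into ``n_outlets`` outlets.
        ``outlet_width`` defaults to ``width / n_outlets``.
    """

    width: float
    height: float
    spiral_radius: float = 5e-3
    n_loops: int = 10
    loop_spacing: float = 300e-6
    n_outlets: int = 5
    outlet_width: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise InvalidGeometryError(
                f"channel dimensions must be positive (w={self.width}, h={self.height})"
            )
        if self.spiral_radius <= 0:
            raise InvalidGeometryError("spiral_radius must be positive")
        if self.n_outlets < 2:
            raise InvalidGeometryError("need at least 2 outlets")
        if self.outlet_width == 0.0:
            object.__setattr__(self, "outlet_width", self.width / self.n_outlets)
        if not math.isclose(self.n_outlets * self.outlet_width, self.width, rel_tol=1e-9):
            raise InvalidGeometryError(
                f"{self.n_outlets} outlets of {self.outlet_width} m do not "
                f"evenly split the {self.width} m channel width"
            )

    @property
    def hydraulic_diameter(self) -> float:
        return hydraulic_diameter(self)

    @property
    def cross_section_area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class Fluid:
    """Newtonian carrier fluid: density (kg/m^3) and dynamic viscosity (Pa s)."""

    density: float
    viscosity: float

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise DomainError("fluid density and viscosity must be positive")


#: water at the conditions used throughout: rho = 1000 kg/m^3, mu = 1e-3 Pa s
WATER = Fluid(density=1000.0, viscosity=1e-3)


def reference_device() -> RectChannel:
    """The 500 um x 220 um, 10-loop, 5-outlet spiral device used in examples."""
    return RectChannel(
        width=500e-6,
        height=220e-6,
        spiral_radius=5e-3,
        n_loops=10,
        loop_spacing=300e-6,
        n_outlets=5,
        outlet_width=100e-6,
    )


@dataclass(frozen=True)
class FlowCondition:
    """Resolved operating point: Q, mean velocity U, Re and De."""

    flow_rate: float
    velocity: float
    reynolds: float
    dean: float


def hydraulic_diameter(channel: RectChannel) -> float:
    """``2hw/(h+w)`` — harmonic-mean scale of the rectangular duct (m)."""
    return 2.0 * channel.height * channel.width / (channel.height + channel.width)


def mean_velocity(flow_rate: float, channel: RectChannel) -> float:
    """Cross-section mean velocity ``Q/(w*h)`` in m/s."""
    if flow_rate < 0:
        raise DomainError(f"flow rate must be non-negative, got {flow_rate}")
    return flow_rate / channel.cross_section_area


def reynolds(fluid: Fluid, velocity: float, diameter: float) -> float:
    """Channel Reynolds number ``rho*U*D/mu``."""
    if diameter <= 0:
        raise InvalidGeometryError("hydraulic diameter must be positive")
    return fluid.density * velocity * diameter / fluid.viscosity


def flow_rate_for_reynolds(re_target: float, fluid: Fluid, channel: RectChannel) -> float:
    """Volumetric flow rate (m^3/s) that produces ``re_target`` in the channel."""
    if re_target <= 0:
        raise DomainError("target Reynolds number must be positive")
    d = hydraulic_diameter(channel)
    u = re_target * fluid.viscosity / (fluid.density * d)
    return u * channel.cross_section_area


def dean_number(re: float, diameter: float, radius: float) -> float:
    """``Re * sqrt(D / 2R)`` — strength of the secondary flow."""
    if radius <= 0:
        raise InvalidGeometryError("radius of curvature must be positive")
    return re * math.sqrt(diameter / (2.0 * radius))


def dean_velocity(de: float) -> float:
    """Empirical lateral (secondary-flow) speed in m/s for Dean number ``de``."""
    if de < 0:
        raise DomainError("Dean number must be non-negative")
    return DEAN_VELOCITY_COEFF * de**DEAN_VELOCITY_EXPONENT


def flow_condition(flow_rate: float, channel: RectChannel, fluid: Fluid) -> FlowCondition:
    """Resolve Q into (Q, U, Re, De) for the channel and fluid."""
    u = mean_velocity(flow_rate, channel)
    re = reynolds(fluid, u, hydraulic_diameter(channel))
    de = dean_number(re, hydraulic_diameter(channel), channel.spiral_radius)
    return FlowCondition(flow_rate=flow_rate, velocity=u, reynolds=re, dean=de)
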