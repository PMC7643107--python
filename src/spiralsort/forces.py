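"""Forces on a particle in the curved channel and their balance diagnostics.

Three forces matter here: the inertial lift ``F_L`` (quartic in particle
diameter), the Dean drag ``F_D`` (linear), and the centrifugal force ``F_c``
(cubic, proportional to the particle/fluid density difference).  Focusing is
diagnosed by the ratio ``R_f = F_L / F_D`` and, for dense particles, by the
balance ``F_L = F_D + F_c``.

The lift expression includes the fluid density factor and the drag expression
the viscosity factor required for dimensional consistency (Stokes drag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError
from .geometry_flow import Fluid


@dataclass(frozen=True)
class ParticleSpec:
    """A particle to be sorted.

    diameter in metres, density in kg/m^3, circularity in (0, 1].
    """

    diameter: float
    density: float
    circularity: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise DomainError(f"particle diameter must be positive, got {self.diameter}")
        if self.density <= 0:
            raise DomainError(f"particle density must be positive, got {self.density}")
        if not 0.0 < self.circularity <= 1.0:
            raise DomainError(f"circularity must be in (0, 1], got {self.circularity}")


@dataclass(frozen=True)
class ForceContext:
    """Position-dependent parameters the force formulas cannot supply themselves.

    ``lift_coefficient`` varies with lateral position; a magnitude of 0.5 is a
    conventional default.  ``tangential_velocity`` defaults to the mean flow
    speed and ``trajectory_radius`` to the channel spiral radius when built via
    :func:`default_context`.
    """

    lift_coefficient: float = 0.5
    tangential_velocity: float = 0.0
    trajectory_radius: float = 5e-3

    def __post_init__(self) -> None:
        if not 0.0 < abs(self.lift_coefficient) <= 1.0:
            raise DomainError("lift coefficient magnitude must be in (0, 1]")
        if self.tangential_velocity < 0:
            raise DomainError("tangential velocity must be non-negative")
        if self.trajectory_radius <= 0:
            raise DomainError("trajectory radius must be positive")


def default_context(velocity: float, radius: float, lift_coefficient: float = 0.5) -> ForceContext:
    """Context with V = mean flow velocity and r = spiral radius."""
    return ForceContext(
        lift_coefficient=lift_coefficient,
        tangential_velocity=velocity,
        trajectory_radius=radius,
    )


def lift_force(
    ctx: ForceContext, fluid: Fluid, velocity: float, diameter: float, hydraulic_diameter: float
) -> float:
    """Net inertial lift ``C_L * rho_f * U^2 * a^4 / D^2`` in newtons."""
    if hydraulic_diameter <= 0:
        raise DomainError("hydraulic diameter must be positive")
    return (
        abs(ctx.lift_coefficient)
        * fluid.density
        * velocity**2
        * diameter**4
        / hydraulic_diameter**2
    )


def dean_drag_force(fluid: Fluid, dean_velocity: float, diameter: float) -> float:
    """Stokes drag of the secondary flow, ``3*pi*mu*U_D*a`` in newtons."""
    if dean_velocity < 0:
        raise DomainError("Dean velocity must be non-negative")
    return 3.0 * math.pi * fluid.viscosity * dean_velocity * diameter


def centrifugal_force(particle: ParticleSpec, fluid: Fluid, ctx: ForceContext) -> float:
    """``(rho_p - rho_f) * pi * V^2 * a^3 / (6r)`` in newtons.

    Zero at neutral buoyancy; negative for particles lighter than the fluid.
    """
    return (
        (particle.density - fluid.density)
        * math.pi
        * ctx.tangential_velocity**2
        * particle.diameter**3
        / (6.0 * ctx.trajectory_radius)
    )


def focusing_ratio(f_lift: float, f_drag: float) -> float:
    """``R_f = F_L / F_D``; the balance point R_f = 1 separates regimes."""
    if f_drag == 0:
        raise DomainError("Dean drag is zero; focusing ratio is undefined")
    return f_lift / f_drag


def required_lift_for_focus(
    particle: ParticleSpec, fluid: Fluid, ctx: ForceContext, dean_velocity: float
) -> float:
    """Lift needed to hold the particle: ``F_D + max(F_c, 0)``.

    For particles at or below the fluid density the centrifugal term vanishes
    and the requirement reduces to the plain drag balance.
    """
    f_d = dean_drag_force(fluid, dean_velocity, particle.diameter)
    f_c = centrifugal_force(particle, fluid, ctx)
    return f_d + max(f_c, 0.0)
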