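"""Closed-form Poiseuille relations for microvessel flow.

Plasma flow in an unobstructed microvessel is pressure-driven laminar flow
with a parabolic velocity profile.  These closed forms serve three roles in
the package: they set the inflow/driving conditions of the pore-transit
simulator, they convert between a Reynolds number and a mean inlet velocity,
and they provide the analytic limit against which the solver is validated.

Two geometries appear.  The circular-pipe forms (``poiseuille_profile``,
``poiseuille_flow_rate``, ``centerline_velocity``) are the classical
Hagen-Poiseuille results for a tube of radius ``R``.  The planar forms
(``planar_profile``, ``pressure_gradient_for_mean_velocity``) are the
parallel-plate equivalents actually used by the 2D channel solver.

Conventions
-----------
All quantities are SI.  ``y`` is the transverse coordinate measured from the
vessel axis, so the walls sit at ``y = +-R``.  A flow in the +x direction
corresponds to a negative pressure gradient ``dp/dx``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChannelSpec",
    "poiseuille_profile",
    "centerline_velocity",
    "poiseuille_flow_rate",
    "mean_velocity_for_Re",
    "reynolds_number",
    "planar_profile",
    "pressure_gradient_for_mean_velocity",
]


@dataclass(frozen=True)
class ChannelSpec:
    """Geometry and fluid properties of a straight vessel segment.

    Parameters
    ----------
    half_width
        Tube radius / channel half-width ``R`` in metres.
    length
        Segment length ``L`` in metres.
    pressure_gradient
        Axial pressure gradient ``dp/dx`` in Pa/m (negative for +x flow).
    viscosity
        Dynamic viscosity ``mu`` in Pa*s.
    density
        Fluid density ``rho`` in kg/m^3.
    """

    half_width: float
    length: float
    pressure_gradient: float
    viscosity: float = 8.0e-4
    density: float = 1000.0

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError(f"half_width must be positive, got {self.half_width}")
        if self.length <= 0:
            raise ValueError(f"length must be positive, got {self.length}")
        if self.viscosity <= 0:
            raise ValueError(f"viscosity must be positive, got {self.viscosity}")
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")


def poiseuille_profile(y, spec: ChannelSpec):
    """Axial velocity ``u(y)`` of fully developed tube flow.

    u(y) = -(1 / 4 mu) * (dp/dx) * (R^2 - y^2)

    Parabolic, symmetric in ``y``, zero at the no-slip walls ``|y| = R`` and
    maximal on the vessel axis.

    Raises
    ------
    ValueError
        If any ``|y| > R`` (outside the vessel lumen).
    """
    y = np.asarray(y, dtype=float)
    R = spec.half_width
    if np.any(np.abs(y) > R * (1 + 1e-12)):
        raise ValueError(f"|y| must not exceed half_width {R}")
    u = -(1.0 / (4.0 * spec.viscosity)) * spec.pressure_gradient * (R**2 - y**2)
    return u if u.ndim else float(u)


def centerline_velocity(spec: ChannelSpec) -> float:
    """Peak (axis) velocity ``u_m = R^2/(4 mu) * (-dp/dx)`` of tube flow."""
    return float(poiseuille_profile(0.0, spec))


def poiseuille_flow_rate(spec: ChannelSpec, dp: float) -> float:
    """Volumetric rate ``Q = pi r^4 dp / (8 eta L)`` through a tube.

    ``dp`` is the (non-negative) pressure drop across the segment length.
    ``Q`` scales with the fourth power of the radius and linearly in ``dp``,
    which is why small stenoses throttle microvascular perfusion so strongly.
    """
    if dp < 0:
        raise ValueError(f"pressure drop must be non-negative, got {dp}")
    r = spec.half_width
    return float(np.pi * r**4 * dp / (8.0 * spec.viscosity * spec.length))


def mean_velocity_for_Re(Re: float, width: float, rho: float, mu: float) -> float:
    """Mean inlet velocity realizing a target Reynolds number.

    The package defines ``Re = rho * ubar * W / mu`` with ``W`` the
    unobstructed channel width and ``ubar`` the mean inlet velocity, so
    ``ubar = Re * mu / (rho * W)``.  ``Re = 0`` maps to a quiescent channel.
    """
    if Re < 0:
        raise ValueError(f"Re must be non-negative, got {Re}")
    if width <= 0 or rho <= 0 or mu <= 0:
        raise ValueError("width, rho and mu must be positive")
    return Re * mu / (rho * width)


def reynolds_number(u_mean: float, width: float, rho: float, mu: float) -> float:
    """Inverse of :func:`mean_velocity_for_Re`."""
    if width <= 0 or rho <= 0 or mu <= 0:
        raise ValueError("width, rho and mu must be positive")
    return rho * u_mean * width / mu


def planar_profile(y, half_width: float, u_mean: float):
    """Plane-Poiseuille profile used as the 2D solver inflow.

    For flow between parallel plates at ``y = +-R`` the mean of the parabola
    is 2/3 of its peak, so ``u(y) = 1.5 * u_mean * (1 - (y/R)^2)``.
    """
    y = np.asarray(y, dtype=float)
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    u = 1.5 * u_mean * (1.0 - (y / half_width) ** 2)
    return u if u.ndim else float(u)


def pressure_gradient_for_mean_velocity(u_mean: float, width: float, mu: float) -> float:
    """Pressure gradient sustaining mean velocity ``u_mean`` between plates.

    Plane Poiseuille flow obeys ``ubar = W^2/(12 mu) * (-dp/dx)`` for plate
    separation ``W``; returns the (negative, for positive ``u_mean``) value
    of ``dp/dx``.
    """
    if width <= 0 or mu <= 0:
        raise ValueError("width and mu must be positive")
    return -12.0 * mu * u_mean / width**2
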