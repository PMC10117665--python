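"""Slender-body viscous torque on a rod-like fish in a straining flow.

A zebrafish larva of length ``L`` and cross-section radius ``a`` is treated
as a rigid slender rod in Stokes flow.  Resistive-force theory gives per-
unit-length drag coefficients

    c_par  = 4*pi*mu / c          c_perp = 8*pi*mu / c
    c      = 2*ln(L/a) - 1        (drag coefficient correction)

The rod pivots about one end held at the stagnation point of the straining
flow ``(u, v) = (eps*x, -eps*y)``; the net viscous torque about the pivot is

    T(theta) = int_0^L s * c_perp * u_theta'(s) ds
             = -(8*pi*mu*eps/c) * (L^3/3) * sin(2*theta)

where ``u_theta' = u_theta - theta_dot * s`` is the circumferential flow
velocity relative to the rotating rod.  The ``[0, L]`` arc-length domain is
what reproduces the ``L^3/3`` prefactor (a centre pivot would give
``L^3/12``); the ``sin(2*theta)`` structure, zeros and stabilities do not
depend on that choice.

For ``eps > 0`` the torque has exactly two zeros per 180-degree period of
the head-tail-symmetric rod: 90 degrees (transverse, source-facing axis),
where a perturbation grows, and 180 degrees (aligned with the inflow/sink
axis), where perturbations decay.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .flow import FlowField, FlowPattern, FluidProperties, velocity_at


@dataclass(frozen=True)
class SlenderBody:
    """Rod geometry: ``length_L`` and cross-section radius ``radius_a`` (m)."""

    length_L: float = 4.0e-3  # ~72 hpf larva
    radius_a: float = 0.25e-3

    def __post_init__(self) -> None:
        if not (self.length_L > 0 and self.radius_a > 0):
            raise ValueError("length_L and radius_a must be > 0")
        if self.length_L / self.radius_a < math.e * (1.0 - 1e-12):
            raise ValueError(
                "aspect ratio L/a must be at least e so that the slender-body "
                "correction c = 2 ln(L/a) - 1 is >= 1"
            )


@dataclass(frozen=True)
class DragCoefficients:
    c_correction: float  # dimensionless
    c_parallel: float  # Pa s (drag per unit length per unit speed)
    c_perp: float  # Pa s; always exactly 2 * c_parallel


@dataclass(frozen=True)
class Equilibrium:
    angle_deg: float  # in (0, 180], modulo head-tail symmetry
    stability: str  # "stable" | "unstable"


def drag_coefficients(body: SlenderBody, fluid: FluidProperties) -> DragCoefficients:
    """Slender-body drag constants for ``body`` in ``fluid``."""
    c = 2.0 * math.log(body.length_L / body.radius_a) - 1.0
    c_par = 4.0 * math.pi * fluid.viscosity_mu / c
    return DragCoefficients(c, c_par, 2.0 * c_par)


def rotational_drag(body: SlenderBody, fluid: FluidProperties) -> float:
    """Rotational drag ``zeta = c_perp * L^3 / 3`` about the end pivot (N m s)."""
    dc = drag_coefficients(body, fluid)
    return dc.c_perp * body.length_L**3 / 3.0


def torque_closed_form(
    body: SlenderBody, fluid: FluidProperties, strain_rate: float, theta
):
    """Closed-form torque ``-(8 pi mu eps / c)(L^3/3) sin(2 theta)`` (N m).

    ``theta`` in radians; scalar or array.
    """
    dc = drag_coefficients(body, fluid)
    pref = (
        8.0
        * math.pi
        * fluid.viscosity_mu
        * strain_rate
        / dc.c_correction
        * body.length_L**3
        / 3.0
    )
    out = -pref * np.sin(2.0 * np.asarray(theta, dtype=float))
    return float(out) if out.ndim == 0 else out


def torque_numeric(
    body: SlenderBody,
    fluid: FluidProperties,
    flow: FlowField,
    pivot: tuple[float, float] = (0.0, 0.0),
    theta: float = 0.0,
    theta_dot: float = 0.0,
    *,
    n_quad: int = 64,
) -> float:
    """Torque by Gauss-Legendre quadrature of ``s * c_perp * u_theta'(s)``.

    The rod spans arc length ``s in [0, L]`` from ``pivot`` in direction
    ``theta``; ``u_theta'`` is the flow's circumferential component about the
    pivot at each rod point minus ``theta_dot * s``.  For polynomial flow
    fields the quadrature is exact to rounding; a rod leaving a bounded
    droplet raises a domain error.
    """
    dc = drag_coefficients(body, fluid)
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    s = 0.5 * body.length_L * (nodes + 1.0)
    w = 0.5 * body.length_L * weights
    ct, st = math.cos(theta), math.sin(theta)
    px = pivot[0] + s * ct
    py = pivot[1] + s * st
    u, v = velocity_at(flow, px, py)  # raises DomainError if outside
    # circumferential direction about the pivot is (-sin theta, cos theta)
    u_theta = -u * st + v * ct
    u_rel = u_theta - theta_dot * s
    return float(np.sum(w * s * dc.c_perp * u_rel))


def equilibria(
    strain_rate: float,
    body: SlenderBody | None = None,
    fluid: FluidProperties | None = None,
) -> list[Equilibrium]:
    """Orientation equilibria of the torque over ``(0, 180]`` degrees.

    Zeros of the closed-form torque are located by sign-change bracketing
    and refined with Brent's method; stability comes from the sign of
    ``dT/dtheta`` at each zero (positive slope => torque amplifies a
    perturbation of the overdamped rod => unstable).  The angles do not
    depend on the strain-rate magnitude; ``strain_rate == 0`` raises because
    the torque vanishes identically.
    """
    if strain_rate == 0:
        raise ValueError("no equilibria: torque is identically zero at eps = 0")
    body = body or SlenderBody()
    fluid = fluid or FluidProperties()

    def t(theta_rad: float) -> float:
        return torque_closed_form(body, fluid, strain_rate, theta_rad)

    # scan (0, 180] degrees; include a point just above 180 to bracket it
    grid = np.deg2rad(np.linspace(0.25, 180.25, 721))
    vals = np.array([t(th) for th in grid])
    zeros: list[float] = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            zeros.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            zeros.append(brentq(t, grid[i], grid[i + 1], xtol=1e-12))
    out = []
    h = 1e-6
    for z in zeros:
        ang = math.degrees(z) % 180.0
        if ang == 0.0:
            ang = 180.0
        slope = (t(z + h) - t(z - h)) / (2 * h)
        out.append(Equilibrium(round(ang, 9), "unstable" if slope > 0 else "stable"))
    out.sort(key=lambda e: e.angle_deg)
    # collapse duplicates from the 180/0 wrap
    dedup: list[Equilibrium] = []
    for e in out:
        if not dedup or abs(e.angle_deg - dedup[-1].angle_deg) > 1e-6:
            dedup.append(e)
    return dedup


def torque_curve(
    body: SlenderBody,
    fluid: FluidProperties,
    strain_rate: float,
    theta_deg: np.ndarray | None = None,
):
    """(theta_deg, torque) arrays of the closed form, for export/plotting."""
    if theta_deg is None:
        theta_deg = np.linspace(0.0, 180.0, 181)
    torque = torque_closed_form(body, fluid, strain_rate, np.deg2rad(theta_deg))
    return np.asarray(theta_deg, dtype=float), torque
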