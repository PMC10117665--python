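"""Orientation dynamics of a trapped slender swimmer.

The droplet trap holds the fish at the stagnation point, so the observable
of interest is its body angle ``theta(t)``.  Dividing the slender-body
torque by the rotational drag makes every material constant cancel, leaving
the passive (anesthetized) relaxation law

    d(theta)/dt = -eps * sin(2*theta)

with stable fixed points on the sink axis (0/180 deg) and unstable ones on
the source axis (90/270 deg).  Active rheotaxis is modelled as the minimal
smooth self-righting drive toward a goal heading ``g`` (default 90 deg, the
upstream/source direction):

    d(theta)/dt = -eps * sin(2*theta) + A * sin(g - theta)

``A`` (1/s) is the activity parameter: ``A = 0`` recovers the passive model
exactly; linearizing at ``theta = g = 90 deg`` gives the decay rate
``A - 2*eps``, so the source heading becomes stable above the critical
activity ``A_crit = 2*eps``.  For ``0 < A < A_crit`` the stable headings
migrate continuously from the sink axis toward the source axis at
``arcsin(A / (2*eps))``, which is what makes the angle a graded mobility
readout.  Rotational noise of diffusivity ``Dr`` (rad^2/s) enters through an
Euler-Maruyama step.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SwimmerParams:
    """Behavioral parameters of the active-rod model.

    activity_A : self-righting angular-rate amplitude (1/s); >= 0.
    goal_angle_deg : preferred heading (deg); default 90, the inward-flow axis.
    rot_noise_Dr : rotational diffusivity (rad^2/s); >= 0.
    """

    activity_A: float = 0.0
    goal_angle_deg: float = 90.0
    rot_noise_Dr: float = 0.0

    def __post_init__(self) -> None:
        if self.activity_A < 0:
            raise ValueError("activity_A must be >= 0")
        if self.rot_noise_Dr < 0:
            raise ValueError("rot_noise_Dr must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    dt: float = 0.05  # s; 20 fps video cadence
    duration_T: float = 300.0  # s
    theta0_deg: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.duration_T < self.dt:
            raise ValueError("duration_T must be >= dt")


@dataclass
class OrientationTrajectory:
    """Sampled heading time series; angles wrapped to [0, 360) degrees."""

    times: np.ndarray
    angles_deg: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.angles_deg):
            raise ValueError("times and angles_deg must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def passive_drift(theta: float, strain_rate: float) -> float:
    """Passive angular velocity ``-eps * sin(2 theta)`` (rad/s), theta in rad."""
    return -strain_rate * math.sin(2.0 * theta)


def active_drift(theta: float, params: SwimmerParams, strain_rate: float) -> float:
    """Active angular velocity: passive flow torque plus self-righting drive."""
    goal = math.radians(params.goal_angle_deg)
    return -strain_rate * math.sin(2.0 * theta) + params.activity_A * math.sin(
        goal - theta
    )


def critical_activity(strain_rate: float) -> float:
    """Activity at which the source heading turns stable: ``2 * eps``."""
    if strain_rate <= 0:
        raise ValueError("strain_rate must be > 0")
    return 2.0 * strain_rate


def simulate(
    params: SwimmerParams,
    config: SimConfig,
    strain_rate: float,
    *,
    activity_fn: Callable[[float], float] | None = None,
) -> OrientationTrajectory:
    """Euler-Maruyama integration of the active-rod Langevin equation.

    ``theta_{k+1} = theta_k + drift(theta_k) dt + sqrt(2 Dr dt) z_k`` with
    standard-normal ``z_k`` from a generator seeded by ``config.seed``; the
    result is bitwise-deterministic for identical inputs.  ``activity_fn``,
    if given, overrides ``params.activity_A`` with a time-dependent value
    ``A(t)`` (used for recovery ramps).

    A step size with ``dt * max|drift| > 0.2`` rad raises: the explicit step
    would be badly resolved.
    """
    a_max = params.activity_A
    if activity_fn is not None:
        a_max = max(abs(activity_fn(t)) for t in (0.0, config.duration_T))
    if config.dt * (abs(strain_rate) + a_max) > 0.2:
        raise ValueError("dt too large for stable explicit integration")

    n = int(round(config.duration_T / config.dt))
    rng = np.random.default_rng(config.seed)
    noise = (
        math.sqrt(2.0 * params.rot_noise_Dr * config.dt) * rng.standard_normal(n)
        if params.rot_noise_Dr > 0
        else np.zeros(n)
    )
    goal = math.radians(params.goal_angle_deg)
    theta = math.radians(config.theta0_deg)
    eps = strain_rate
    dt = config.dt
    out = np.empty(n + 1)
    out[0] = theta
    t = 0.0
    for k in range(n):
        a = params.activity_A if activity_fn is None else activity_fn(t)
        drift = -eps * math.sin(2.0 * theta) + a * math.sin(goal - theta)
        theta = (theta + drift * dt + noise[k]) % TWO_PI
        out[k + 1] = theta
        t += dt
    times = np.arange(n + 1) * dt
    meta = {
        "params": asdict(params),
        "config": asdict(config),
        "strain_rate": strain_rate,
        "time_varying_activity": activity_fn is not None,
    }
    return OrientationTrajectory(times, np.degrees(out) % 360.0, meta)


@dataclass(frozen=True)
class ActivityEstimate:
    a_hat: float  # clipped at zero (activity is a non-negative rate)
    se: float
    a_hat_raw: float = 0.0  # unclipped OLS coefficient, for bias checks
    strain_rate_hat: float | None = None


def _wrapped_diff(angles_rad: np.ndarray) -> np.ndarray:
    d = np.diff(angles_rad)
    return (d + math.pi) % TWO_PI - math.pi


def estimate_activity(
    traj: OrientationTrajectory,
    strain_rate: float,
    *,
    goal_angle_deg: float = 90.0,
    fit_strain: bool = False,
) -> ActivityEstimate:
    """Recover the activity ``A`` from a trajectory by drift regression.

    The finite-difference angular velocity is regressed on the drift
    regressors ``[-sin(2 theta), sin(goal - theta)]``.  With
    ``fit_strain=False`` the strain coefficient is fixed at the known
    ``eps`` and only ``A`` is estimated; otherwise both are co-estimated by
    least squares.  The returned ``a_hat`` is clipped at zero (activity is a
    non-negative rate); ``se`` is the OLS standard error of the unclipped
    coefficient.
    """
    if len(traj.times) < 100:
        raise ValueError("need >= 100 samples to estimate activity")
    th = np.radians(traj.angles_deg)
    dt = np.diff(traj.times)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("trajectory must be uniformly sampled")
    y = _wrapped_diff(th) / dt
    th_l = th[:-1]
    goal = math.radians(goal_angle_deg)
    x_act = np.sin(goal - th_l)
    if float(np.var(x_act)) < 1e-12 and float(np.mean(x_act**2)) < 1e-12:
        raise ValueError("unidentifiable: swimmer pinned at the goal heading")
    if fit_strain:
        X = np.column_stack([-np.sin(2.0 * th_l), x_act])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(len(y) - 2, 1)
        cov = np.linalg.inv(X.T @ X) * float(resid @ resid) / dof
        return ActivityEstimate(
            max(float(beta[1]), 0.0),
            math.sqrt(cov[1, 1]),
            float(beta[1]),
            float(beta[0]),
        )
    y_adj = y + strain_rate * np.sin(2.0 * th_l)
    sxx = float(x_act @ x_act)
    a = float(x_act @ y_adj) / sxx
    resid = y_adj - a * x_act
    dof = max(len(y) - 1, 1)
    se = math.sqrt(float(resid @ resid) / dof / sxx)
    return ActivityEstimate(max(a, 0.0), se, a)


def measure_critical_activity(
    strain_rate: float,
    *,
    theta0_deg: float = 91.0,
    duration: float = 200.0,
    dt: float = 0.01,
    tol_deg: float = 2.0,
    rel_tol: float = 5e-3,
    bracket: tuple[float, float] | None = None,
) -> float:
    """Measure ``A_crit`` by bisection on noiseless simulations.

    From ``theta0`` just off the source heading, a supercritical swimmer
    relaxes back to 90 deg while a subcritical one slides to the migrated
    equilibrium ``180 - arcsin(A/2 eps)``; the final distance from 90 deg
    separates the two regimes.  Bisection runs until the bracket is within
    ``rel_tol`` relative width.
    """
    lo, hi = bracket if bracket is not None else (0.5 * strain_rate, 4.0 * strain_rate)

    def holds_source(a: float) -> bool:
        traj = simulate(
            SwimmerParams(activity_A=a, rot_noise_Dr=0.0),
            SimConfig(dt=dt, duration_T=duration, theta0_deg=theta0_deg, seed=0),
            strain_rate,
        )
        final = traj.angles_deg[-1]
        dev = abs((final - 90.0 + 180.0) % 360.0 - 180.0)
        return dev < tol_deg

    if holds_source(lo) or not holds_source(hi):
        raise ValueError("bracket does not straddle the bifurcation")
    while (hi - lo) / hi > rel_tol:
        mid = 0.5 * (lo + hi)
        if holds_source(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
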