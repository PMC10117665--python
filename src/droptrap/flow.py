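"""In-droplet recirculating flow fields.

A sessile droplet on a vibrated substrate develops steady internal
recirculation whose topology (one, two or four closed cells) depends on the
drive frequency.  Near the centre of the four-cell pattern the flow is well
approximated by the planar straining flow ``(u, v) = (eps*x, -eps*y)`` with a
stagnation point at the droplet centre: outflow along the x axis (the
"source" axis) and inflow along the y axis (the "sink-feeding" axis).

The bounded patterns are the lowest-order streamfunction modes in a disk of
radius ``R`` that satisfy no-penetration on the rim and have the required
cell counts::

    one_cell           psi = (eps/2) * (R^2 - r^2)          (solid rotation)
    two_cell           psi = eps * R * y * (1 - r^2/R^2)
    four_cell_bounded  psi = eps * x * y * (1 - r^2/R^2)

with ``(u, v) = (d(psi)/dy, -d(psi)/dx)``, so every field is exactly
divergence free and the rim ``r = R`` is a streamline.  The four-cell mode
reduces to the pure straining flow as ``r/R -> 0``.  The one-cell mode is the
solid-rotation profile rather than a mode with zero rim slip: a single
recirculation cell with single-signed vorticity is impossible without
tangential slip at the rim (and slip is physical at a free droplet surface).

Angles at public interfaces are degrees, measured counterclockwise from the
positive x axis; positions are metres; internal math is radians/SI.
"""
from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage


class DomainError(ValueError):
    """A point (or a body) lies outside the droplet."""


class FlowPattern(str, enum.Enum):
    PURE_STRAIN = "pure_strain"
    ONE_CELL = "one_cell"
    TWO_CELL = "two_cell"
    FOUR_CELL_BOUNDED = "four_cell_bounded"


#: vibration-frequency bands that produce each pattern (metadata only; the
#: vibration physics itself is not modelled)
FREQUENCY_BANDS_HZ = {
    FlowPattern.ONE_CELL: (22.0, 35.0),
    FlowPattern.TWO_CELL: (36.0, 47.0),
    FlowPattern.FOUR_CELL_BOUNDED: (48.0, 53.0),
}


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid; ``viscosity_mu`` is the dynamic viscosity in Pa s."""

    viscosity_mu: float = 1.0e-3  # water at ~20 C

    def __post_init__(self) -> None:
        if not self.viscosity_mu > 0:
            raise ValueError("viscosity_mu must be > 0")


@dataclass(frozen=True)
class FlowField:
    """A parametric in-droplet velocity field.

    Parameters
    ----------
    pattern:
        One of :class:`FlowPattern`.
    strain_rate:
        Amplitude parameter ``eps`` (1/s) for every pattern; for
        ``pure_strain`` it is the literal strain rate.
    droplet_radius:
        Droplet radius ``R`` (m).  Ignored by ``pure_strain`` except as the
        bounding box used by :func:`sample_grid`.
    center:
        Droplet centre in physical coordinates (m).
    """

    pattern: FlowPattern = FlowPattern.FOUR_CELL_BOUNDED
    strain_rate: float = 1.0
    droplet_radius: float = 6.0e-3  # 12 mm droplet
    center: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.strain_rate):
            raise ValueError("strain_rate must be finite")
        if self.pattern is not FlowPattern.PURE_STRAIN and not self.droplet_radius > 0:
            raise ValueError("droplet_radius must be > 0 for bounded patterns")

    @property
    def bounded(self) -> bool:
        return self.pattern is not FlowPattern.PURE_STRAIN


def velocity_at(flow: FlowField, x, y, *, check_domain: bool = True):
    """Velocity components ``(u, v)`` (m/s) at physical position(s) ``(x, y)``.

    Accepts scalars or numpy arrays.  For bounded patterns a point outside
    the droplet disk raises :class:`DomainError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cx, cy = flow.center
    xr = x - cx
    yr = y - cy
    eps = flow.strain_rate
    R = flow.droplet_radius

    if flow.bounded and check_domain:
        r2 = xr * xr + yr * yr
        if np.any(r2 > R * R * (1.0 + 1e-12)):
            raise DomainError("point outside droplet of radius %g m" % R)

    if flow.pattern is FlowPattern.PURE_STRAIN:
        u, v = eps * xr, -eps * yr
    elif flow.pattern is FlowPattern.ONE_CELL:
        # psi = (eps/2)(R^2 - r^2): solid rotation, |u| = eps*r
        u, v = -eps * yr, eps * xr
    elif flow.pattern is FlowPattern.TWO_CELL:
        # psi = eps*R*y*(1 - r^2/R^2)
        u = eps * R * (1.0 - (xr * xr + 3.0 * yr * yr) / (R * R))
        v = 2.0 * eps * xr * yr / R
    elif flow.pattern is FlowPattern.FOUR_CELL_BOUNDED:
        # psi = eps*x*y*(1 - r^2/R^2)
        u = eps * xr * (1.0 - (xr * xr + 3.0 * yr * yr) / (R * R))
        v = -eps * yr * (1.0 - (3.0 * xr * xr + yr * yr) / (R * R))
    else:  # pragma: no cover
        raise ValueError(f"unknown pattern {flow.pattern}")
    if x.ndim == 0:
        return float(u), float(v)
    return u, v


def streamfunction_at(flow: FlowField, x, y):
    """Analytic streamfunction ``psi`` at ``(x, y)`` (reference/oracle use)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cx, cy = flow.center
    xr, yr = x - cx, y - cy
    r2 = xr * xr + yr * yr
    eps, R = flow.strain_rate, flow.droplet_radius
    if flow.pattern is FlowPattern.PURE_STRAIN:
        return eps * xr * yr
    if flow.pattern is FlowPattern.ONE_CELL:
        return 0.5 * eps * (R * R - r2)
    if flow.pattern is FlowPattern.TWO_CELL:
        return eps * R * yr * (1.0 - r2 / (R * R))
    if flow.pattern is FlowPattern.FOUR_CELL_BOUNDED:
        return eps * xr * yr * (1.0 - r2 / (R * R))
    raise ValueError(f"unknown pattern {flow.pattern}")  # pragma: no cover


def polar_components(u, v, phi):
    """Rotate Cartesian velocity into polar components at polar angle ``phi``.

    Returns ``(u_r, u_theta)`` with ``u_r = u cos(phi) + v sin(phi)`` and
    ``u_theta = -u sin(phi) + v cos(phi)``; the Euclidean norm is preserved.
    ``phi`` is in radians.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c, s = np.cos(phi), np.sin(phi)
    u_r = u * c + v * s
    u_t = -u * s + v * c
    if u.ndim == 0 and np.ndim(u_t) == 0:
        return float(u_r), float(u_t)
    return u_r, u_t


@dataclass
class VelocityGrid:
    """Velocity field sampled on a uniform rectangular grid.

    ``u``, ``v`` and ``mask`` are 2-D arrays indexed ``[iy, ix]``; ``mask``
    flags nodes inside the droplet.
    """

    x_coords: np.ndarray  # (nx,)
    y_coords: np.ndarray  # (ny,)
    u: np.ndarray  # (ny, nx)
    v: np.ndarray  # (ny, nx)
    mask: np.ndarray  # (ny, nx) bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ny, nx = self.u.shape
        if self.v.shape != (ny, nx) or self.mask.shape != (ny, nx):
            raise ValueError("u, v, mask shapes must agree")
        if len(self.x_coords) != nx or len(self.y_coords) != ny:
            raise ValueError("coordinate lengths inconsistent with field shape")
        if not np.all(np.isfinite(self.u[self.mask])) or not np.all(
            np.isfinite(self.v[self.mask])
        ):
            raise ValueError("non-finite velocities on masked-in nodes")


def sample_grid(flow: FlowField, n_per_axis: int = 64) -> VelocityGrid:
    """Sample ``flow`` on an ``n x n`` grid over the droplet bounding box.

    Nodes outside the droplet disk are masked out (zero-filled velocities).
    """
    if n_per_axis < 8:
        raise ValueError("n_per_axis must be >= 8")
    cx, cy = flow.center
    R = flow.droplet_radius
    x = np.linspace(cx - R, cx + R, n_per_axis)
    y = np.linspace(cy - R, cy + R, n_per_axis)
    X, Y = np.meshgrid(x, y)
    if flow.bounded:
        mask = (X - cx) ** 2 + (Y - cy) ** 2 <= R * R
    else:
        mask = np.ones_like(X, dtype=bool)
    u = np.zeros_like(X)
    v = np.zeros_like(X)
    uu, vv = velocity_at(flow, X[mask], Y[mask], check_domain=False)
    u[mask], v[mask] = uu, vv
    meta = {
        "pattern": flow.pattern.value,
        "strain_rate": flow.strain_rate,
        "droplet_radius": flow.droplet_radius,
        "center": list(flow.center),
        "n_per_axis": n_per_axis,
    }
    meta.update(flow.meta)
    return VelocityGrid(x, y, u, v, mask, meta)


def integrate_streamfunction(grid: VelocityGrid) -> np.ndarray:
    """Reconstruct ``psi`` on the grid by trapezoidal path integration.

    ``-v`` is integrated along x on the first row, then ``u`` along y down
    each column (``u = d(psi)/dy``, ``v = -d(psi)/dx``).  Masked-out nodes
    contribute zero velocity, which is consistent with the rim being a
    streamline for bounded fields.
    """
    u = np.where(grid.mask, grid.u, 0.0)
    v = np.where(grid.mask, grid.v, 0.0)
    x, y = grid.x_coords, grid.y_coords
    ny = len(y)
    j0 = ny // 2  # reference row through the droplet centre: the
    # integration path stays inside the disk as long as possible
    psi = np.zeros_like(u)
    dx = np.diff(x)
    psi[j0, 1:] = -np.cumsum(0.5 * (v[j0, 1:] + v[j0, :-1]) * dx)
    dy = np.diff(y)
    up = np.cumsum(0.5 * (u[j0 + 1 :, :] + u[j0:-1, :]) * dy[j0:, None], axis=0)
    psi[j0 + 1 :, :] = psi[j0, :][None, :] + up
    down = np.cumsum(
        0.5 * (u[j0 - 1 :: -1, :] + u[j0:0:-1, :]) * dy[j0 - 1 :: -1, None], axis=0
    )
    psi[j0 - 1 :: -1, :] = psi[j0, :][None, :] - down
    return psi


def _count_extrema(psi_s: np.ndarray, mask: np.ndarray) -> int:
    """Count extremal plateaus of ``psi_s`` with a full 3x3 footprint in mask."""
    interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool))
    mx = ndimage.maximum_filter(psi_s, size=3)
    mn = ndimage.minimum_filter(psi_s, size=3)
    is_max = (psi_s >= mx) & interior
    is_min = (psi_s <= mn) & interior
    n = 0
    for flags in (is_max, is_min):
        _, k = ndimage.label(flags, structure=np.ones((3, 3), int))
        n += k
    return n


def classify_pattern(
    grid: VelocityGrid, *, smooth_sigma: float = 1.0, degenerate_tol: float = 1e-12
) -> tuple[str, int]:
    """Classify a sampled velocity grid by recirculation-cell count.

    The streamfunction is reconstructed by path integration, smoothed with a
    Gaussian of ``smooth_sigma`` grid cells, and its interior extrema are
    counted (one per closed recirculation cell).  Returns ``(label, n_cells)``
    with label ``one_cell``/``two_cell``/``four_cell`` for counts 1/2/4 and
    ``random`` otherwise; a near-zero field gives ``("random", 0)``.
    """
    ny, nx = grid.u.shape
    if min(nx, ny) < 32:
        raise ValueError("classification requires >= 32 nodes per axis")
    speed = np.hypot(grid.u, grid.v)[grid.mask]
    if speed.size == 0 or float(speed.max()) <= degenerate_tol:
        return "random", 0
    psi = integrate_streamfunction(grid)
    psi_s = ndimage.gaussian_filter(psi, sigma=smooth_sigma)
    n = _count_extrema(psi_s, grid.mask)
    label = {1: "one_cell", 2: "two_cell", 4: "four_cell"}.get(n, "random")
    return label, n


# ---------------------------------------------------------------------------
# serialization: long-format CSV + JSON sidecar


def save_grid(grid: VelocityGrid, csv_path: str | Path) -> Path:
    csv_path = Path(csv_path)
    X, Y = np.meshgrid(grid.x_coords, grid.y_coords)
    df = pd.DataFrame(
        {
            "x": X.ravel(),
            "y": Y.ravel(),
            "u": grid.u.ravel(),
            "v": grid.v.ravel(),
            "inside": grid.mask.ravel().astype(int),
        }
    )
    df.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps(grid.meta, indent=2))
    return csv_path


def load_grid(csv_path: str | Path) -> VelocityGrid:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    x = np.unique(df["x"].to_numpy())
    y = np.unique(df["y"].to_numpy())
    nx, ny = len(x), len(y)
    order = np.lexsort((df["x"].to_numpy(), df["y"].to_numpy()))
    u = df["u"].to_numpy()[order].reshape(ny, nx)
    v = df["v"].to_numpy()[order].reshape(ny, nx)
    mask = df["inside"].to_numpy()[order].reshape(ny, nx).astype(bool)
    sidecar = csv_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return VelocityGrid(x, y, u, v, mask, meta)
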