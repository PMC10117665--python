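"""Centroid detection, frame linking and track-based velocimetry.

This is the analysis counterpart of the video pipeline: fish/tracer blobs
are segmented by a relative global threshold and connected components,
localized by intensity-weighted centroids (orientation from second image
moments, modulo 180 degrees), linked frame-to-frame by optimal bipartite
assignment on displacement, and tracer displacements are binned into a
:class:`~droptrap.flow.VelocityGrid` (particle-tracking velocimetry).

Pixel convention: origin at the top-left, ``x`` rightward (columns), ``y``
downward (rows), pixel centres at integer coordinates.  Conversion to
physical coordinates flips ``y`` and applies ``px_scale`` so that angles
agree with the flow-model convention (counterclockwise from +x).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import griddata
from scipy.optimize import linear_sum_assignment
from skimage import measure

from .flow import VelocityGrid


@dataclass
class FrameStack:
    """T x H x W intensity stack with acquisition metadata."""

    frames: np.ndarray
    frame_rate: float  # fps
    px_scale: float  # m per pixel
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be T x H x W with T >= 2")
        if not np.all(np.isfinite(self.frames)) or np.any(self.frames < 0):
            raise ValueError("intensities must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass(frozen=True)
class Detection:
    frame_index: int
    x_px: float
    y_px: float
    area_px: int
    orientation_deg: float | None = None  # physical convention, modulo 180


@dataclass
class TrackedTrajectory:
    """One linked object: per-frame times and physical positions."""

    track_id: int
    frame_indices: np.ndarray
    times_s: np.ndarray
    x_m: np.ndarray
    y_m: np.ndarray
    orientation_deg: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.frame_indices)


def _moments_orientation(win: np.ndarray, cx: float, cy: float) -> float:
    """Principal-axis angle (deg, physical convention, mod 180) of a blob.

    ``win`` holds intensities, (cx, cy) the weighted centroid in window
    pixel coordinates.  Image-coordinate angles (y down) are negated to get
    the physical (y up) convention.
    """
    ys, xs = np.nonzero(win > 0)
    w = win[ys, xs]
    dx = xs - cx
    dy = ys - cy
    m20 = float(np.sum(w * dx * dx))
    m02 = float(np.sum(w * dy * dy))
    m11 = float(np.sum(w * dx * dy))
    ang_img = 0.5 * math.atan2(2.0 * m11, m20 - m02)
    return (-math.degrees(ang_img)) % 180.0


def detect(
    frame: np.ndarray,
    threshold: float = 0.5,
    min_area: int = 4,
    *,
    frame_index: int = 0,
    with_orientation: bool = False,
    resolve_head: bool = False,
) -> list[Detection]:
    """Segment one frame into blob detections.

    The frame is thresholded at ``threshold * max(frame)`` (scale invariant),
    8-connected components of at least ``min_area`` pixels become detections
    with intensity-weighted centroids.  A blank frame yields an empty list.

    Orientation from second image moments is inherently modulo 180.  With
    ``resolve_head=True`` the intensity skew along the principal axis breaks
    the tie (the brighter end is taken as the head) and the orientation is
    reported in [0, 360); off by default because it only makes sense for
    blobs with a genuine brightness asymmetry.
    """
    frame = np.asarray(frame, dtype=float)
    vmax = float(frame.max(initial=0.0))
    if vmax <= 0:
        return []
    bw = frame >= threshold * vmax
    labels = measure.label(bw, connectivity=2)
    dets: list[Detection] = []
    for region in measure.regionprops(labels, intensity_image=frame):
        if region.area < min_area:
            continue
        win = np.where(region.image, region.image_intensity, 0.0)
        tot = float(win.sum())
        ys, xs = np.nonzero(win > 0)
        cx = float(np.sum(win[ys, xs] * xs)) / tot
        cy = float(np.sum(win[ys, xs] * ys)) / tot
        r0, c0, _, _ = region.bbox
        ori = None
        if with_orientation:
            ori = _moments_orientation(win, cx, cy)
            if resolve_head:
                # project pixel offsets on the axis (physical y up => -dy);
                # a brighter head packs intensity near the +axis tip, which
                # skews the along-axis profile: negative third moment about
                # the weighted centroid means the head is on the +axis side
                ys, xs = np.nonzero(win > 0)
                w = win[ys, xs]
                th = math.radians(ori)
                proj = (xs - cx) * math.cos(th) + (cy - ys) * math.sin(th)
                if float(np.sum(w * proj**3)) > 0:
                    ori = (ori + 180.0) % 360.0
        dets.append(
            Detection(frame_index, c0 + cx, r0 + cy, int(region.area), ori)
        )
    dets.sort(key=lambda d: (d.x_px, d.y_px))
    return dets


def detect_stack(
    stack: FrameStack,
    threshold: float = 0.5,
    min_area: int = 4,
    *,
    with_orientation: bool = False,
) -> list[list[Detection]]:
    """Run :func:`detect` over every frame of a stack."""
    return [
        detect(
            f,
            threshold,
            min_area,
            frame_index=i,
            with_orientation=with_orientation,
        )
        for i, f in enumerate(stack.frames)
    ]


def link(
    detections_per_frame: list[list[Detection]],
    max_disp: float = 10.0,
) -> list[list[Detection]]:
    """Link detections across consecutive frames into identity-stable tracks.

    Frame-to-frame correspondence minimizes total displacement (optimal
    bipartite assignment); pairs farther than ``max_disp`` px are rejected
    and start new tracks.  There is no gap closing: a missed frame splits a
    track.  Detections are sorted within each frame, so the result is
    invariant to input order; cost ties resolve to the lowest combined
    index.

    Returns one list of detections per track, ordered by frame.
    """
    tracks: list[list[Detection]] = []
    open_idx: list[int] = []  # indices into `tracks` still extendable
    prev_frame = None
    for dets in detections_per_frame:
        dets = sorted(dets, key=lambda d: (d.x_px, d.y_px))
        frame = dets[0].frame_index if dets else (
            prev_frame + 1 if prev_frame is not None else 0
        )
        # close tracks that skipped a frame
        open_idx = [
            i for i in open_idx if tracks[i][-1].frame_index == frame - 1
        ]
        assigned = set()
        if open_idx and dets:
            cost = np.zeros((len(open_idx), len(dets)))
            for a, ti in enumerate(open_idx):
                last = tracks[ti][-1]
                for b, d in enumerate(dets):
                    cost[a, b] = math.hypot(d.x_px - last.x_px, d.y_px - last.y_px)
            big = max_disp * 1e6 + 1.0
            cost_capped = np.where(cost <= max_disp, cost, big)
            rows, cols = linear_sum_assignment(cost_capped)
            for a, b in zip(rows, cols):
                if cost[a, b] <= max_disp:
                    tracks[open_idx[a]].append(dets[b])
                    assigned.add(b)
        new_open = [i for i in open_idx if tracks[i][-1].frame_index == frame]
        for b, d in enumerate(dets):
            if b not in assigned:
                tracks.append([d])
                new_open.append(len(tracks) - 1)
        open_idx = new_open
        prev_frame = frame
    return tracks


def tracks_to_physical(
    track_dets: list[list[Detection]], stack: FrameStack
) -> list[TrackedTrajectory]:
    """Convert pixel-space linked detections into physical trajectories."""
    H = stack.shape[1]
    out = []
    for tid, dets in enumerate(track_dets):
        frames = np.array([d.frame_index for d in dets])
        oris = (
            np.array([d.orientation_deg for d in dets], dtype=float)
            if all(d.orientation_deg is not None for d in dets)
            else None
        )
        out.append(
            TrackedTrajectory(
                track_id=tid,
                frame_indices=frames,
                times_s=frames / stack.frame_rate,
                x_m=np.array([d.x_px for d in dets]) * stack.px_scale,
                y_m=(H - 1 - np.array([d.y_px for d in dets])) * stack.px_scale,
                orientation_deg=oris,
            )
        )
    return out


def track_stack(
    stack: FrameStack,
    threshold: float = 0.5,
    min_area: int = 4,
    max_disp: float = 10.0,
    *,
    with_orientation: bool = False,
) -> list[TrackedTrajectory]:
    """detect -> link -> physical units, in one call."""
    dets = detect_stack(
        stack, threshold, min_area, with_orientation=with_orientation
    )
    return tracks_to_physical(link(dets, max_disp), stack)


def velocity_grid_from_tracks(
    tracks: list[TrackedTrajectory],
    *,
    n_per_axis: int = 32,
    extent: tuple[float, float, float, float] | None = None,
    fill_missing: bool = False,
    meta: dict | None = None,
) -> VelocityGrid:
    """Bin per-step track velocities into a mean-velocity grid (PTV).

    Each consecutive detection pair contributes one velocity sample
    ``(dx/dt, dy/dt)`` located at the step midpoint; cell values are sample
    means and cells without samples are masked out (optionally filled by
    nearest-neighbour interpolation but left masked).
    """
    xs, ys, us, vs = [], [], [], []
    for tr in tracks:
        if len(tr) < 2:
            continue
        dt = np.diff(tr.times_s)
        good = dt > 0
        u = np.diff(tr.x_m) / dt
        v = np.diff(tr.y_m) / dt
        xs.append((0.5 * (tr.x_m[1:] + tr.x_m[:-1]))[good])
        ys.append((0.5 * (tr.y_m[1:] + tr.y_m[:-1]))[good])
        us.append(u[good])
        vs.append(v[good])
    if not xs:
        raise ValueError("need at least one displacement sample")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    u = np.concatenate(us)
    v = np.concatenate(vs)
    if extent is None:
        extent = (x.min(), x.max(), y.min(), y.max())
    x0, x1, y0, y1 = extent
    xspan = x1 - x0 if x1 > x0 else 1.0  # degenerate extent: single column
    yspan = y1 - y0 if y1 > y0 else 1.0
    xg = np.linspace(x0, x0 + xspan, n_per_axis) if x1 <= x0 else np.linspace(x0, x1, n_per_axis)
    yg = np.linspace(y0, y0 + yspan, n_per_axis) if y1 <= y0 else np.linspace(y0, y1, n_per_axis)
    ix = np.clip(np.rint((x - x0) / xspan * (n_per_axis - 1)), 0, n_per_axis - 1).astype(int)
    iy = np.clip(np.rint((y - y0) / yspan * (n_per_axis - 1)), 0, n_per_axis - 1).astype(int)
    usum = np.zeros((n_per_axis, n_per_axis))
    vsum = np.zeros_like(usum)
    cnt = np.zeros_like(usum)
    np.add.at(usum, (iy, ix), u)
    np.add.at(vsum, (iy, ix), v)
    np.add.at(cnt, (iy, ix), 1.0)
    occupied = cnt > 0
    with np.errstate(invalid="ignore"):
        um = np.where(occupied, usum / np.maximum(cnt, 1), 0.0)
        vm = np.where(occupied, vsum / np.maximum(cnt, 1), 0.0)
    mask = occupied
    if fill_missing and not occupied.all():
        Xg, Yg = np.meshgrid(xg, yg)
        pts = np.column_stack([Xg[occupied], Yg[occupied]])
        um = griddata(pts, um[occupied], (Xg, Yg), method="nearest")
        vm = griddata(pts, vm[occupied], (Xg, Yg), method="nearest")
    return VelocityGrid(xg, yg, um, vm, mask, meta or {"source": "ptv"})


def fill_grid_to_disk(
    grid: VelocityGrid, center: tuple[float, float], radius: float
) -> VelocityGrid:
    """Return a copy masked to a droplet disk, empty in-disk cells filled by
    nearest-neighbour interpolation from occupied cells (for classification)."""
    Xg, Yg = np.meshgrid(grid.x_coords, grid.y_coords)
    disk = (Xg - center[0]) ** 2 + (Yg - center[1]) ** 2 <= radius**2
    occ = grid.mask
    pts = np.column_stack([Xg[occ], Yg[occ]])
    u = griddata(pts, grid.u[occ], (Xg, Yg), method="nearest")
    v = griddata(pts, grid.v[occ], (Xg, Yg), method="nearest")
    u = np.where(disk, u, 0.0)
    v = np.where(disk, v, 0.0)
    return VelocityGrid(grid.x_coords, grid.y_coords, u, v, disk, dict(grid.meta))


def tracks_to_dataframe(tracks: list[TrackedTrajectory]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for k in range(len(tr)):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": int(tr.frame_indices[k]),
                    "time_s": float(tr.times_s[k]),
                    "x_m": float(tr.x_m[k]),
                    "y_m": float(tr.y_m[k]),
                    "orientation_deg": (
                        float(tr.orientation_deg[k])
                        if tr.orientation_deg is not None
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def save_tracks(tracks: list[TrackedTrajectory], path: str | Path) -> Path:
    path = Path(path)
    tracks_to_dataframe(tracks).to_csv(path, index=False)
    return path


def load_tracks(path: str | Path) -> list[TrackedTrajectory]:
    df = pd.read_csv(path)
    out = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        ori = g["orientation_deg"].to_numpy()
        out.append(
            TrackedTrajectory(
                track_id=int(tid),
                frame_indices=g["frame"].to_numpy(dtype=int),
                times_s=g["time_s"].to_numpy(dtype=float),
                x_m=g["x_m"].to_numpy(dtype=float),
                y_m=g["y_m"].to_numpy(dtype=float),
                orientation_deg=None if np.all(np.isnan(ori)) else ori,
            )
        )
    return out
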