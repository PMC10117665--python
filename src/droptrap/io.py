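"""File round-trips: trajectories as CSV + JSON meta, stacks as TIFF/PNG."""
from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .swimmer import OrientationTrajectory
from .tracking import FrameStack


def save_trajectory(traj: OrientationTrajectory, csv_path: str | Path) -> Path:
    csv_path = Path(csv_path)
    pd.DataFrame({"time_s": traj.times, "angle_deg": traj.angles_deg}).to_csv(
        csv_path, index=False
    )
    csv_path.with_suffix(".json").write_text(json.dumps(traj.meta, indent=2))
    return csv_path


def load_trajectory(csv_path: str | Path) -> OrientationTrajectory:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar = csv_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return OrientationTrajectory(
        df["time_s"].to_numpy(float), df["angle_deg"].to_numpy(float), meta
    )


def save_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF (float32) with JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    meta = {"frame_rate": stack.frame_rate, "px_scale": stack.px_scale}
    meta.update(stack.meta)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def load_stack(
    path: str | Path,
    frame_rate: float | None = None,
    px_scale: float | None = None,
) -> FrameStack:
    """Read a multi-page TIFF or a PNG sequence directory into a FrameStack.

    Acquisition metadata comes from the JSON sidecar when present; explicit
    arguments override it.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames in {path}")
        frames = np.stack([iio.imread(f).astype(float) for f in files])
    else:
        frames = np.asarray(tifffile.imread(path), dtype=float)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    fr = frame_rate if frame_rate is not None else meta.get("frame_rate")
    px = px_scale if px_scale is not None else meta.get("px_scale")
    if fr is None or px is None:
        raise ValueError("frame_rate and px_scale must be given or in sidecar")
    return FrameStack(frames, float(fr), float(px), meta)
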