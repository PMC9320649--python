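"""Reading frames and writing run outputs (TIFF stacks, CSVs, PNG masks)."""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .forward_solver import StateTrajectory
from .geometry import FORCE_CSV_COLUMNS, EulerTrace
from .imaging import ImageFrame

__all__ = [
    "load_frames",
    "save_field_stack",
    "load_field_stack",
    "save_trajectory",
    "write_forces_csv",
    "write_euler_csv",
    "save_mask_png",
]


def load_frames(path, pixel_size: float, frame_interval: float = 1.0) -> list:
    """Load a movie as ImageFrames from a multi-page TIFF or a directory.

    A directory is read as sorted numbered PNG/TIFF frames; intensities are
    rescaled to [0, 1] floats.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        # synthetic movie folders hold frame_*.png next to ground-truth masks
        frame_files = [p for p in files if p.stem.startswith("frame")]
        if frame_files:
            files = frame_files
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames under {path}")
        stack = [iio.imread(f) for f in files]
    else:
        arr = tifffile.imread(path) if path.suffix.lower() in {".tif", ".tiff"} else iio.imread(path)
        stack = list(arr) if arr.ndim == 3 else [arr]
    frames = []
    for i, img in enumerate(stack):
        img = np.asarray(img, dtype=float)
        if img.ndim == 3:  # collapse RGB(A)
            img = img[..., :3].mean(axis=-1)
        if img.max() > 1.0:
            img = img / 255.0
        frames.append(ImageFrame(img, pixel_size=pixel_size, index=i, timestamp=i * frame_interval))
    return frames


def save_field_stack(fields: np.ndarray, path) -> None:
    """Write a (k, n, n) stack of fields as a 32-bit float multi-page TIFF."""
    tifffile.imwrite(
        path,
        np.asarray(fields, dtype=np.float32),
        photometric="minisblack",
        planarconfig="contig",
    )


def load_field_stack(path) -> np.ndarray:
    arr = tifffile.imread(path)
    return arr[None] if arr.ndim == 2 else arr


def save_trajectory(traj: StateTrajectory, stem) -> tuple[Path, Path]:
    """Export a trajectory as <stem>.tif (states) + <stem>.csv (step, t, lambda, mass)."""
    stem = Path(stem)
    tif = stem.with_suffix(".tif")
    csv = stem.with_suffix(".csv")
    save_field_stack(traj.states, tif)
    lam = np.concatenate([[np.nan], traj.lambdas]) if traj.stride == 1 else np.full(traj.states.shape[0], np.nan)
    pd.DataFrame(
        {
            "step": np.arange(traj.states.shape[0]),
            "t": traj.times,
            "lambda": lam[: traj.states.shape[0]],
            "mass": traj.states.mean(axis=(1, 2)),
        }
    ).to_csv(csv, index=False)
    return tif, csv


def write_forces_csv(rows, path) -> None:
    """Per-frame-pair force summary CSV in the canonical column order."""
    df = pd.DataFrame([r.as_dict() for r in rows])
    df = df[FORCE_CSV_COLUMNS]
    df.to_csv(path, index=False)


def write_euler_csv(trace: EulerTrace, path) -> None:
    pd.DataFrame(
        {
            "step": np.arange(len(trace.values)),
            "t": trace.times,
            "euler_number": trace.values,
            "cell_count": trace.rounded,
        }
    ).to_csv(path, index=False)


def save_mask_png(mask: np.ndarray, path) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=np.uint8) * 255))
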