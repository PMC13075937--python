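"""Readers and writers: frame stacks, trajectory tables, legacy exports.

All tabular outputs are UTF-8 CSV with a header row; angles are degrees,
times seconds, positions millimetres — one convention everywhere.  Video
frame stacks are 8-bit grayscale; lossless interchange formats are
multipage TIFF and ``.npy``, with AVI accepted/produced through imageio
whenever a codec plugin is installed.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v2 as iio
import numpy as np
import pandas as pd
import yaml

from .arena import ArenaLayout
from .flight import HeadingSeries
from .walking import FilteredTrajectory, RawTrajectory, Trajectory


def write_frames(path, frames: np.ndarray, fps: float = 20.0) -> None:
    """Write an (n, h, w) uint8 stack as .npy, multipage .tif, or .avi."""
    path = Path(path)
    frames = np.asarray(frames)
    if path.suffix == ".npy":
        np.save(path, frames)
    elif path.suffix in (".tif", ".tiff"):
        iio.mimwrite(path, list(frames))
    elif path.suffix == ".avi":
        writer = iio.get_writer(path, fps=fps)  # needs an ffmpeg/pyav plugin
        for f in frames:
            writer.append_data(f)
        writer.close()
    else:
        raise ValueError(f"unsupported frame-stack format: {path.suffix!r}")


def read_frames(path) -> np.ndarray:
    """Read a frame stack; color input is luma-converted with a warning."""
    path = Path(path)
    if path.suffix == ".npy":
        frames = np.load(path)
    else:
        frames = np.asarray(iio.mimread(path, memtest=False))
    if frames.ndim == 4:  # color
        warnings.warn("color video converted to grayscale (ITU-R 601 luma)")
        frames = (
            0.299 * frames[..., 0] + 0.587 * frames[..., 1] + 0.114 * frames[..., 2]
        )
        frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    return frames


def write_trajectory(path, traj: Trajectory) -> None:
    traj.to_frame().to_csv(path, index=False)


def read_trajectory(path, roi_id: int = 0) -> Trajectory | FilteredTrajectory:
    df = pd.read_csv(path)
    common = dict(
        roi_id=roi_id,
        time=df["time_s"].to_numpy(),
        x=df["x_mm"].to_numpy(),
        y=df["y_mm"].to_numpy(),
        detected=df["detected"].to_numpy(dtype=bool),
    )
    if "updated" in df.columns:
        return FilteredTrajectory(**common, updated=df["updated"].to_numpy(dtype=bool))
    return Trajectory(**common)


def write_heading_series(path, series: HeadingSeries) -> None:
    series.to_frame().to_csv(path, index=False)


def read_heading_series(path) -> HeadingSeries:
    df = pd.read_csv(path)
    return HeadingSeries(
        time=df["time_s"].to_numpy(),
        heading=df["heading_deg"].to_numpy(),
        flying=df["flying"].to_numpy(dtype=bool),
        axis_angle=df["axis_deg"].to_numpy() if "axis_deg" in df else None,
        flagged=df["flagged"].to_numpy(dtype=bool) if "flagged" in df else None,
    )


def write_layout(path, layout: ArenaLayout) -> None:
    layout.to_frame().to_csv(path, index=False)


def read_layout(path, arena_diameter_mm: float) -> ArenaLayout:
    return ArenaLayout.from_frame(pd.read_csv(path), arena_diameter_mm)


LEGACY_DIALECT_VERSION = 1


def write_legacy_pair(stem, raw: RawTrajectory, rate: float, mm_per_px: float) -> None:
    """Legacy paired export: .DAT holds tab-separated per-frame x/y (px),
    .TXT a key: value metadata header.

    The dialect of the historical analysis software is not published; this
    export is versioned (``dialect_version`` in the .TXT) and documented
    rather than asserted bit-compatible with it.
    """
    stem = Path(stem)
    dat = stem.with_suffix(".DAT")
    txt = stem.with_suffix(".TXT")
    with open(dat, "w", encoding="utf-8") as fh:
        for x, y in zip(raw.x_px, raw.y_px):
            fh.write(f"{x:.3f}\t{y:.3f}\n")
    meta = {
        "dialect_version": LEGACY_DIALECT_VERSION,
        "roi_id": raw.roi_id,
        "n_frames": len(raw),
        "frame_rate_hz": rate,
        "mm_per_px": mm_per_px,
        "columns": "x_px\ty_px",
    }
    with open(txt, "w", encoding="utf-8") as fh:
        for k, v in meta.items():
            fh.write(f"{k}: {v}\n")


def read_legacy_pair(stem) -> tuple[np.ndarray, dict]:
    stem = Path(stem)
    arr = np.loadtxt(stem.with_suffix(".DAT"), delimiter="\t", ndmin=2)
    meta = {}
    for line in stem.with_suffix(".TXT").read_text(encoding="utf-8").splitlines():
        k, _, v = line.partition(": ")
        meta[k] = v
    return arr, meta


def load_config(path) -> dict:
    """Run configuration from YAML or JSON."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
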