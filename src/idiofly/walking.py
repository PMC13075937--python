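"""Single-fly-per-arena centroid tracking for walking assays.

The tracker assumes exactly one dark fly per region of interest on a bright
back-lit platform.  Per frame the background image is subtracted, the
difference thresholded, and the centroid of the thresholded pixels stored.
If several objects appear in a roi (pixel noise), the one closest to the
fly's previous position wins; if none appears, the last known position is
held until the fly is found again.  Raw pixel trajectories are converted to
mm in arena coordinates and finally passed through a walking filter that
only advances the stored position when the fly moved at least a threshold
distance (default 0.8 mm/frame), so that sub-threshold jitter never counts
as walking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .arena import ArenaLayout, Roi

#: default position-update threshold, mm per frame
WALKING_THRESHOLD_MM = 0.8
#: default background-difference detection threshold, gray levels
DEFAULT_DETECTION_THRESHOLD = 25.0
#: default minimum blob area, px^2
DEFAULT_MIN_BLOB_AREA = 4


@dataclass
class RawTrajectory:
    """Per-frame pixel centroids for one roi; held frames keep the last fix."""

    roi_id: int
    x_px: np.ndarray
    y_px: np.ndarray
    detected: np.ndarray  # bool per frame
    n_candidates: np.ndarray  # blobs seen per frame

    def __len__(self) -> int:
        return len(self.x_px)


@dataclass
class Trajectory:
    """Planar path in mm, arena coordinates (origin = roi centre, y up)."""

    roi_id: int
    time: np.ndarray  # s
    x: np.ndarray  # mm
    y: np.ndarray  # mm
    detected: np.ndarray
    state: np.ndarray | None = None  # optional ground-truth walk flag (simulation)

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "frame": np.arange(len(self.time)),
                "time_s": self.time,
                "x_mm": self.x,
                "y_mm": self.y,
                "detected": self.detected.astype(bool),
            }
        )
        return df


@dataclass
class FilteredTrajectory(Trajectory):
    """Trajectory after the walking filter; ``updated`` marks advancing frames."""

    updated: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = super().to_frame()
        df["updated"] = self.updated.astype(bool)
        return df


def _roi_window(roi: Roi, shape: tuple[int, int]) -> tuple[slice, slice]:
    r = roi.radius_px
    y0 = max(0, int(np.floor(roi.cy - r)))
    y1 = min(shape[0], int(np.ceil(roi.cy + r)) + 1)
    x0 = max(0, int(np.floor(roi.cx - r)))
    x1 = min(shape[1], int(np.ceil(roi.cx + r)) + 1)
    return slice(y0, y1), slice(x0, x1)


def track_walking(
    frames,
    background: np.ndarray,
    layout: ArenaLayout,
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD,
    min_blob_area: int = DEFAULT_MIN_BLOB_AREA,
) -> list[RawTrajectory]:
    """Track one fly in every roi across a frame stack.

    ``frames`` is any iterable of 2-D uint8 arrays (all the same shape as
    ``background``).  Returns one :class:`RawTrajectory` per roi, each with
    exactly one entry per frame: detection gaps are filled by holding the
    last known position (or back-filling the first detection for frames
    before the fly was ever seen).
    """
    background = np.asarray(background, dtype=np.int16)
    if len(layout) == 0:
        raise ValueError("layout contains no rois")

    rois = list(layout)
    windows = [_roi_window(r, background.shape) for r in rois]
    masks = []
    for r, (ys, xs) in zip(rois, windows):
        yy, xx = np.mgrid[ys, xs]
        masks.append((xx - r.cx) ** 2 + (yy - r.cy) ** 2 <= r.radius_px**2)

    n_rois = len(rois)
    xs_out: list[list[float]] = [[] for _ in range(n_rois)]
    ys_out: list[list[float]] = [[] for _ in range(n_rois)]
    det_out: list[list[bool]] = [[] for _ in range(n_rois)]
    cand_out: list[list[int]] = [[] for _ in range(n_rois)]
    prev: list[tuple[float, float] | None] = [None] * n_rois

    n_frames = 0
    for frame in frames:
        frame = np.asarray(frame)
        if frame.shape != background.shape:
            raise ValueError(
                f"frame shape {frame.shape} does not match background {background.shape}"
            )
        n_frames += 1
        diff = np.abs(background - frame.astype(np.int16))
        for i, (roi, (ys, xs), mask) in enumerate(zip(rois, windows, masks)):
            sub = diff[ys, xs]
            fg = (sub > detection_threshold) & mask
            labeled, n_blobs = ndimage.label(fg)
            centroid = None
            n_keep = 0
            if n_blobs:
                areas = ndimage.sum_labels(fg, labeled, index=np.arange(1, n_blobs + 1))
                keep = np.flatnonzero(areas >= min_blob_area) + 1
                n_keep = len(keep)
                if n_keep == 1:
                    cy, cx = ndimage.center_of_mass(fg, labeled, keep[0])
                    centroid = (xs.start + cx, ys.start + cy)
                elif n_keep > 1:
                    cents = ndimage.center_of_mass(fg, labeled, keep)
                    cents = [(xs.start + c[1], ys.start + c[0]) for c in cents]
                    ref = prev[i] if prev[i] is not None else (roi.cx, roi.cy)
                    d2 = [(c[0] - ref[0]) ** 2 + (c[1] - ref[1]) ** 2 for c in cents]
                    # nearest-previous wins; exact ties fall to the lowest label
                    centroid = cents[int(np.argmin(d2))]
            if centroid is not None:
                prev[i] = centroid
                xs_out[i].append(centroid[0])
                ys_out[i].append(centroid[1])
                det_out[i].append(True)
            else:
                held = prev[i] if prev[i] is not None else (np.nan, np.nan)
                xs_out[i].append(held[0])
                ys_out[i].append(held[1])
                det_out[i].append(False)
            cand_out[i].append(n_keep)

    result = []
    for i, roi in enumerate(rois):
        x = np.array(xs_out[i])
        y = np.array(ys_out[i])
        det = np.array(det_out[i], dtype=bool)
        # frames before the first detection are back-filled with it
        if det.any():
            first = int(np.argmax(det))
            x[:first] = x[first]
            y[:first] = y[first]
        result.append(
            RawTrajectory(
                roi_id=roi.id,
                x_px=x,
                y_px=y,
                detected=det,
                n_candidates=np.array(cand_out[i]),
            )
        )
    return result


def to_mm(raw: RawTrajectory, layout: ArenaLayout, rate: float) -> Trajectory:
    """Convert a pixel trajectory to mm in arena coordinates.

    Arena coordinates have their origin at the roi centre with x to the
    right and y up (mathematical convention), so image-y is negated.
    Time is frame index over the frame rate.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    roi = layout.roi(raw.roi_id)
    n = len(raw)
    return Trajectory(
        roi_id=raw.roi_id,
        time=np.arange(n) / rate,
        x=(raw.x_px - roi.cx) * roi.mm_per_px,
        y=-(raw.y_px - roi.cy) * roi.mm_per_px,
        detected=raw.detected.copy(),
    )


def walking_filter(traj: Trajectory, tau: float = WALKING_THRESHOLD_MM) -> FilteredTrajectory:
    """Suppress sub-threshold jitter by holding the position between walks.

    The stored position advances to the current sample only when that sample
    lies at least ``tau`` mm from the last *updated* position (the anchor);
    otherwise the anchor is carried forward.  Measuring from the anchor
    rather than the previous raw frame means slow drift below ``tau`` never
    accumulates into a spurious update.  Idempotent: filtering an already
    filtered trajectory changes nothing.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    n = len(traj)
    x = np.empty(n)
    y = np.empty(n)
    updated = np.zeros(n, dtype=bool)
    ax, ay = traj.x[0], traj.y[0]
    x[0], y[0] = ax, ay
    updated[0] = True  # first frame establishes the anchor
    for i in range(1, n):
        if np.hypot(traj.x[i] - ax, traj.y[i] - ay) >= tau:
            ax, ay = traj.x[i], traj.y[i]
            updated[i] = True
        x[i], y[i] = ax, ay
    return FilteredTrajectory(
        roi_id=traj.roi_id,
        time=traj.time.copy(),
        x=x,
        y=y,
        detected=traj.detected.copy(),
        state=None if traj.state is None else traj.state.copy(),
        updated=updated,
    )
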