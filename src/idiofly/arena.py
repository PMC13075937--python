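"""Arena geometry: lens undistortion, background model, and ROI detection.

Multi-arena platforms film many small bright (back-lit) arenas with a single
camera, so the tracker first needs to know where each arena sits in the image
and how large a pixel is in millimetres.  Arenas are detected by adaptive
thresholding of a bright-on-dark frame, filtered by area, and sorted
row-major (top row first, left to right) so that arena ids are stable across
runs and match the physical loading order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_local
from skimage.measure import label, regionprops

#: physical sizes used by the assays, mm
CLASSIC_PLATFORM_DIAMETER_MM = 120.0
MULTI_ARENA_DIAMETER_MM = 49.0
YMAZE_ARM_LENGTH_MM = 13.5


@dataclass(frozen=True)
class Roi:
    """One tracked region: a circular platform or a Y-maze footprint.

    ``radius_px`` holds the fitted circle radius for circles and the arm
    length (max centroid-to-pixel distance) for Y-mazes.
    """

    id: int
    shape: str  # "circle" | "y-maze"
    cx: float
    cy: float
    radius_px: float
    row: int
    col: int
    mm_per_px: float

    def contains(self, x: float, y: float, pad: float = 0.0) -> bool:
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= (self.radius_px + pad) ** 2


@dataclass
class ArenaLayout:
    rois: list[Roi]
    arena_diameter_mm: float
    frame_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.rois]
        if len(ids) != len(set(ids)):
            raise ValueError("roi ids must be unique")

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def roi(self, roi_id: int) -> Roi:
        for r in self.rois:
            if r.id == roi_id:
                return r
        raise KeyError(f"no roi with id {roi_id}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": r.id,
                    "shape": r.shape,
                    "cx_px": r.cx,
                    "cy_px": r.cy,
                    "radius_px": r.radius_px,
                    "row": r.row,
                    "col": r.col,
                    "mm_per_px": r.mm_per_px,
                }
                for r in self.rois
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, arena_diameter_mm: float) -> "ArenaLayout":
        rois = [
            Roi(
                id=int(row["id"]),
                shape=str(row["shape"]),
                cx=float(row["cx_px"]),
                cy=float(row["cy_px"]),
                radius_px=float(row["radius_px"]),
                row=int(row["row"]),
                col=int(row["col"]),
                mm_per_px=float(row["mm_per_px"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(rois=rois, arena_diameter_mm=arena_diameter_mm)


@dataclass(frozen=True)
class CalibrationModel:
    """Pinhole intrinsics plus Brown–Conrady distortion coefficients.

    The camera matrix is ``[[fx, 0, cx], [0, fy, cy], [0, 0, 1]]``;
    distortion is ``(k1, k2, p1, p2, k3)`` — radial k-terms, tangential
    p-terms.  Coefficients come from an external checkerboard calibration;
    estimating them is out of scope here.
    """

    camera_matrix: np.ndarray
    dist_coeffs: tuple[float, float, float, float, float] = (0.0, 0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        K = np.asarray(self.camera_matrix, dtype=float)
        if K.shape != (3, 3):
            raise ValueError("camera matrix must be 3x3")
        if K[0, 0] <= 0 or K[1, 1] <= 0:
            raise ValueError("focal terms must be positive")
        object.__setattr__(self, "camera_matrix", K)
        if len(self.dist_coeffs) != 5:
            raise ValueError("expected 5 distortion coefficients (k1,k2,p1,p2,k3)")

    @classmethod
    def identity(cls, frame_shape: tuple[int, int]) -> "CalibrationModel":
        h, w = frame_shape
        f = float(max(h, w))
        K = np.array([[f, 0.0, (w - 1) / 2.0], [0.0, f, (h - 1) / 2.0], [0.0, 0.0, 1.0]])
        return cls(camera_matrix=K)

    def distort_points(self, xy: np.ndarray) -> np.ndarray:
        """Map ideal (undistorted) pixel coords to observed (distorted) ones."""
        K = self.camera_matrix
        k1, k2, p1, p2, k3 = self.dist_coeffs
        x = (xy[..., 0] - K[0, 2]) / K[0, 0]
        y = (xy[..., 1] - K[1, 2]) / K[1, 1]
        r2 = x * x + y * y
        radial = 1.0 + k1 * r2 + k2 * r2**2 + k3 * r2**3
        xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
        yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
        out = np.empty_like(xy, dtype=float)
        out[..., 0] = xd * K[0, 0] + K[0, 2]
        out[..., 1] = yd * K[1, 1] + K[1, 2]
        return out


def undistort_frame(frame: np.ndarray, calibration: CalibrationModel) -> np.ndarray:
    """Resample ``frame`` onto the ideal (distortion-free) pixel grid.

    For every output pixel the forward Brown–Conrady model gives the source
    location in the observed frame, which is sampled bilinearly.  With all
    coefficients zero the remap is the identity.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    if all(c == 0.0 for c in calibration.dist_coeffs):
        return frame.copy()
    h, w = frame.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    pts = np.stack([xx, yy], axis=-1)
    src = calibration.distort_points(pts)
    sampled = ndimage.map_coordinates(
        frame.astype(float), [src[..., 1], src[..., 0]], order=1, mode="nearest"
    )
    if np.issubdtype(frame.dtype, np.integer):
        info = np.iinfo(frame.dtype)
        return np.clip(np.rint(sampled), info.min, info.max).astype(frame.dtype)
    return sampled.astype(frame.dtype)


def build_background(first: np.ndarray, last: np.ndarray) -> np.ndarray:
    """Per-pixel maximum of a video's first and last frames.

    Flies are dark on a bright back-light, so a fly that moved between the two
    frames disappears from the maximum image, which then shows the empty
    arenas only.
    """
    first = np.asarray(first)
    last = np.asarray(last)
    if first.shape != last.shape:
        raise ValueError(f"frame shape mismatch: {first.shape} vs {last.shape}")
    return np.maximum(first, last)


def _cluster_rows(cys: np.ndarray, tol: float) -> np.ndarray:
    """1-D clustering of centroid-y into row indices, tolerance ``tol`` px."""
    order = np.argsort(cys)
    rows = np.empty(len(cys), dtype=int)
    current_row = 0
    anchor = cys[order[0]]
    for idx in order:
        if cys[idx] - anchor > tol:
            current_row += 1
            anchor = cys[idx]
        rows[idx] = current_row
    return rows


def detect_rois(
    frame: np.ndarray,
    expected_count: int,
    shape: str = "circle",
    arena_diameter_mm: float | None = None,
    area_bounds: tuple[float, float] | None = None,
    block_size: int | None = None,
) -> ArenaLayout:
    """Detect bright arenas on a dark surround and return a sorted layout.

    Adaptive (local-mean) thresholding finds bright components; components
    outside ``area_bounds`` (px^2) are dropped; survivors must match
    ``expected_count`` exactly.  Rois are ordered row-major by clustering
    centroid-y with a tolerance of half the median roi diameter.

    ``mm_per_px`` is fitted per roi from the known physical size:
    circle diameter (49 mm multi-arena, 120 mm classic platform) or the
    13.5 mm Y-maze arm length.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("expected a single grayscale frame")
    if expected_count < 1:
        raise ValueError("expected_count must be >= 1")
    if arena_diameter_mm is None:
        arena_diameter_mm = (
            MULTI_ARENA_DIAMETER_MM if expected_count > 1 else CLASSIC_PLATFORM_DIAMETER_MM
        )

    if block_size is None:
        block_size = int(min(frame.shape) / 8)
    block_size = max(3, block_size | 1)  # odd
    thr = threshold_local(frame, block_size=block_size, method="mean", mode="reflect")
    # offset by a fraction of the global dynamic range so flat dark regions
    # do not threshold on noise
    offset = 0.05 * (frame.max() - frame.min())
    mask = frame > (thr + offset)
    mask = ndimage.binary_fill_holes(mask)

    labeled = label(mask)
    props = regionprops(labeled)
    if area_bounds is None:
        # arenas should all be about the same size; keep components within
        # a factor of 4 of the largest to reject specks
        areas = sorted((p.area for p in props), reverse=True)
        if not areas:
            raise ValueError(f"found 0 candidate rois, expected {expected_count}")
        area_bounds = (areas[0] / 4.0, areas[0] * 4.0)
    keep = [p for p in props if area_bounds[0] <= p.area <= area_bounds[1]]
    if len(keep) != expected_count:
        raise ValueError(
            f"found {len(keep)} rois matching area bounds, expected {expected_count}"
        )

    cxs = np.array([p.centroid[1] for p in keep])
    cys = np.array([p.centroid[0] for p in keep])
    if shape == "circle":
        radii = np.array([np.sqrt(p.area / np.pi) for p in keep])
        mm_per_px = arena_diameter_mm / (2.0 * radii)
    elif shape == "y-maze":
        radii = np.empty(len(keep))
        for i, p in enumerate(keep):
            rr, cc = p.coords[:, 0], p.coords[:, 1]
            radii[i] = np.sqrt((rr - p.centroid[0]) ** 2 + (cc - p.centroid[1]) ** 2).max()
        mm_per_px = YMAZE_ARM_LENGTH_MM / radii
    else:
        raise ValueError(f"unknown roi shape: {shape!r}")

    tol = float(np.median(2.0 * radii)) / 2.0
    rows = _cluster_rows(cys, tol)
    # row-major sort: row index ascending then centroid-x; sorting key is a
    # pure function of the centroid coordinates, independent of label order
    order = np.lexsort((cxs, rows))
    rois = []
    col_counter: dict[int, int] = {}
    for new_id, idx in enumerate(order):
        r = int(rows[idx])
        c = col_counter.get(r, 0)
        col_counter[r] = c + 1
        rois.append(
            Roi(
                id=new_id,
                shape=shape,
                cx=float(cxs[idx]),
                cy=float(cys[idx]),
                radius_px=float(radii[idx]),
                row=r,
                col=c,
                mm_per_px=float(mm_per_px[idx]),
            )
        )
    return ArenaLayout(rois=rois, arena_diameter_mm=arena_diameter_mm, frame_shape=frame.shape)
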