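"""Heading tracking for tethered flying flies.

A magneto-tethered fly is filmed from below as a dark silhouette on a bright
back-light and can rotate freely about its yaw axis.  Each frame is
segmented at two Gaussian blur scales: a strong blur suppresses legs and
wings so that thresholding yields the body alone; subtracting the body from
the weak-blur mask leaves the appendages.  The body's best-fit ellipse gives
an axis in [0, 180); the head end is then assigned to whichever half-plane
along the axis carries the smaller pixel sum (head plus thorax are narrower
than abdomen), extending the heading to [0, 360).  Visible wings in the
appendage mask mark frames where the fly stopped flying.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian

#: optomotor pre-test stimulus rotation, deg/s
OPTOMOTOR_PRETEST_DEG_S = 120.0
#: native tracking rate of the rig, frames/s
FLIGHT_TRACKING_RATE_HZ = 90.0


@dataclass(frozen=True)
class FlightSegmentation:
    body_mask: np.ndarray
    appendage_mask: np.ndarray


@dataclass(frozen=True)
class FlightConfig:
    """Segmentation and wing-detection settings.

    Sigmas are tuned for a body roughly 60 px long and scale linearly with
    fly size; ``threshold`` is the gray-level cut below which blurred pixels
    count as fly (dark silhouette).  A frame is scored as not flying when
    the appendage pixels in the lateral sectors exceed ``wing_fraction`` of
    the body pixel count.
    """

    strong_sigma: float = 8.0
    weak_sigma: float = 2.0
    threshold: float = 128.0
    wing_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not self.strong_sigma > self.weak_sigma >= 0:
            raise ValueError("need strong_sigma > weak_sigma >= 0")


@dataclass
class HeadingSeries:
    """Per-frame heading of one fly, degrees in [0, 360), plus flight flag."""

    time: np.ndarray  # s
    heading: np.ndarray  # deg, [0, 360)
    flying: np.ndarray  # bool
    axis_angle: np.ndarray | None = None  # deg, [0, 180)
    flagged: np.ndarray | None = None  # degenerate / tie frames

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "time_s": self.time,
                "heading_deg": self.heading,
                "flying": self.flying.astype(bool),
            }
        )
        if self.axis_angle is not None:
            df["axis_deg"] = self.axis_angle
        if self.flagged is not None:
            df["flagged"] = self.flagged.astype(bool)
        return df


class FlyNotFound(ValueError):
    """No body pixels survive thresholding in a frame."""


def segment_fly(frame: np.ndarray, config: FlightConfig = FlightConfig()) -> FlightSegmentation:
    """Two-scale segmentation of a dark fly on a bright background."""
    frame = np.asarray(frame, dtype=float)
    strong = gaussian(frame, sigma=config.strong_sigma, preserve_range=True)
    weak = gaussian(frame, sigma=config.weak_sigma, preserve_range=True)
    body = strong < config.threshold
    if not body.any():
        raise FlyNotFound("no body pixels below threshold")
    appendages = (weak < config.threshold) & ~body
    return FlightSegmentation(body_mask=body, appendage_mask=appendages)


class DegenerateAxis(ValueError):
    """Mask is isotropic; the ellipse orientation is undefined."""


def body_axis(body_mask: np.ndarray) -> float:
    """Orientation of the mask's best-fit ellipse, degrees in [0, 180).

    Computed from second central moments, counter-clockwise from image +x
    (image y points down, so the row coordinate is negated).
    """
    ys, xs = np.nonzero(body_mask)
    if len(xs) < 5:
        raise ValueError("mask needs at least 5 pixels")
    x = xs - xs.mean()
    y = -(ys - ys.mean())  # math convention, y up
    mu20 = np.mean(x * x)
    mu02 = np.mean(y * y)
    mu11 = np.mean(x * y)
    if np.isclose(mu20, mu02) and np.isclose(mu11, 0.0):
        raise DegenerateAxis("isotropic mask, orientation undefined")
    angle = 0.5 * np.degrees(np.arctan2(2.0 * mu11, mu20 - mu02))
    return float(angle % 180.0)


def resolve_heading(body_mask: np.ndarray, axis: float, previous: float | None = None):
    """Disambiguate head vs tail, returning (heading deg in [0,360), tie flag).

    The mask is centred on its centroid and rotated so the axis lies along
    +x; the half-plane (x > 0 vs x < 0) with the *smaller* pixel sum holds
    the head, because head and thorax are narrower than the abdomen.  On an
    exact tie the side of ``previous`` is kept and the frame flagged.
    """
    ys, xs = np.nonzero(body_mask)
    x = xs - xs.mean()
    y = -(ys - ys.mean())
    t = np.radians(axis)
    x_rot = x * np.cos(t) + y * np.sin(t)
    pos = int(np.sum(x_rot > 0))
    neg = int(np.sum(x_rot < 0))
    if pos == neg:
        if previous is None:
            return float(axis % 360.0), True
        # keep the side closest to the previous heading
        cand = (axis % 360.0, (axis + 180.0) % 360.0)
        d = [abs((c - previous + 180.0) % 360.0 - 180.0) for c in cand]
        return float(cand[int(np.argmin(d))]), True
    heading = axis if pos < neg else axis + 180.0
    return float(heading % 360.0), False


def _wing_pixels(segmentation: FlightSegmentation, heading: float) -> int:
    """Appendage pixels in the lateral sectors (45–135 deg off the body axis)."""
    ys, xs = np.nonzero(segmentation.appendage_mask)
    if len(xs) == 0:
        return 0
    bys, bxs = np.nonzero(segmentation.body_mask)
    cx, cy = bxs.mean(), bys.mean()
    ang = np.degrees(np.arctan2(-(ys - cy), xs - cx))  # y up
    off = np.abs((ang - heading + 180.0) % 360.0 - 180.0)
    lateral = (off >= 45.0) & (off <= 135.0)
    return int(np.sum(lateral))


def track_flight(
    frames,
    config: FlightConfig = FlightConfig(),
    rate: float = FLIGHT_TRACKING_RATE_HZ,
) -> HeadingSeries:
    """Per-frame heading series from a stack of close-up silhouette frames.

    Degenerate or fly-not-found frames carry the previous heading and are
    flagged; a run where more than half the frames fail is rejected
    outright.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    headings: list[float] = []
    axes: list[float] = []
    flying: list[bool] = []
    flags: list[bool] = []
    prev_heading: float | None = None
    n_failed = 0
    for frame in frames:
        try:
            seg = segment_fly(frame, config)
            axis = body_axis(seg.body_mask)
            heading, tie = resolve_heading(seg.body_mask, axis, previous=prev_heading)
            n_body = int(seg.body_mask.sum())
            wings = _wing_pixels(seg, heading)
            is_flying = wings < config.wing_fraction * n_body
            flagged = tie
        except (FlyNotFound, DegenerateAxis):
            n_failed += 1
            heading = prev_heading if prev_heading is not None else 0.0
            axis = heading % 180.0
            is_flying = False
            flagged = True
        prev_heading = heading
        headings.append(heading)
        axes.append(axis)
        flying.append(is_flying)
        flags.append(flagged)
    n = len(headings)
    if n == 0:
        raise ValueError("empty frame stack")
    if n_failed > 0.5 * n:
        raise RuntimeError(f"tracking failed: {n_failed}/{n} frames without a fly")
    return HeadingSeries(
        time=np.arange(n) / rate,
        heading=np.asarray(headings),
        flying=np.asarray(flying, dtype=bool),
        axis_angle=np.asarray(axes),
        flagged=np.asarray(flags, dtype=bool),
    )


def unwrap_headings(heading_deg: np.ndarray | HeadingSeries) -> np.ndarray:
    """Continuous (unbounded) heading: shortest-arc differences, cumulated.

    Successive differences are mapped to (-180, 180] and summed from the
    first sample, so full rotations accumulate instead of wrapping.
    """
    h = heading_deg.heading if isinstance(heading_deg, HeadingSeries) else np.asarray(heading_deg, dtype=float)
    if h.size == 0:
        raise ValueError("empty heading series")
    diffs = np.diff(h)
    diffs = -((-diffs + 180.0) % 360.0 - 180.0)  # maps to (-180, 180]
    return np.concatenate([[h[0]], h[0] + np.cumsum(diffs)])
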