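"""Synthetic flies: trajectories, heading series, videos, and cohort tables.

Every downstream stage — arena detection, the walking and flight trackers,
the behavioral parameters, and the individuality statistics — is exercised
against data generated here with known ground truth, so the whole pipeline
is testable without any recordings.

Three generators, one renderer:

* :func:`simulate_walk` — a two-state (walk/pause) correlated random walk
  inside a circular arena with optional pull toward the stimulus axis and
  toward the wall.  This is a declared test fixture, not a model of fly
  locomotion.
* :func:`simulate_flight_headings` — mean-reverting heading fluctuation
  around a fly-specific preferred axis, or constant drift in optomotor
  mode, with optional non-flying bouts.
* :func:`simulate_cohort` — a long-format trait table with fly-specific
  random intercepts, context fixed effects, and residual noise: exactly the
  variance structure a random-intercept mixed model assumes.
* :func:`render_video` / :func:`render_flight_video` — 8-bit grayscale
  frame stacks of dark anti-aliased fly bodies on bright back-lit arenas
  (or a close-up silhouette for the tethered rig), in one-to-one frame
  correspondence with the generating trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arena import ArenaLayout, Roi
from .flight import HeadingSeries
from .walking import Trajectory

#: factor columns of a cohort table, with their numeric coding ranges
FACTOR_COLUMNS = ("day", "temperature", "stripes", "light", "arena")


@dataclass(frozen=True)
class LatentFlyProfile:
    """Stable fly-specific locomotor traits (the simulated 'individuality')."""

    fly_id: int
    base_speed: float = 10.0  # mm/s while walking
    activity: float = 0.5  # stationary fraction of time in the walk state
    stripe_attraction: float = 0.0  # fractional per-step pull toward the stripe axis
    edge_bias: float = 0.0  # fractional per-step pull toward the wall
    turn_noise: float = 20.0  # deg, sd of per-step direction change

    def __post_init__(self) -> None:
        if self.base_speed <= 0:
            raise ValueError("base_speed must be > 0")
        if not 0.0 <= self.activity <= 1.0:
            raise ValueError("activity must be in [0, 1]")
        for name in ("stripe_attraction", "edge_bias", "turn_noise"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")


@dataclass(frozen=True)
class ContextModifier:
    """One environmental context and how it modulates latent traits.

    Factor levels follow the numeric coding used throughout: day 1-3,
    temperature in deg C, 0-2 stripes, light off (0) / on (1), round arena
    (0) / y-maze (1).  ``rank_disruption`` is the fraction of between-fly
    variance replaced by fresh noise in this context: 0 preserves the
    flies' rank order perfectly, 1 destroys it.
    """

    context_id: str = "baseline"
    day: int = 1
    temperature: float = 25.0
    stripes: int = 2
    light: int = 1
    arena: int = 0
    modality: str = "walk"
    speed_scale: float = 1.0
    activity_shift: float = 0.0
    attraction_scale: float = 1.0
    rank_disruption: float = 0.0

    def __post_init__(self) -> None:
        if self.speed_scale <= 0:
            raise ValueError("speed_scale must be > 0")
        if not 0.0 <= self.rank_disruption <= 1.0:
            raise ValueError("rank_disruption must be in [0, 1]")
        if self.attraction_scale < 0:
            raise ValueError("attraction_scale must be >= 0")

    def factor_codes(self) -> dict[str, float]:
        return {
            "day": float(self.day),
            "temperature": float(self.temperature),
            "stripes": float(self.stripes),
            "light": float(self.light),
            "arena": float(self.arena),
        }


@dataclass(frozen=True)
class VarianceComponents:
    """Between-fly and residual variance plus fixed-effect slopes."""

    sigma2_between: float
    sigma2_within: float
    fixed_effects: dict[str, float] = field(default_factory=dict)
    grand_mean: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma2_between) or self.sigma2_between < 0:
            raise ValueError("sigma2_between must be finite and >= 0")
        if not np.isfinite(self.sigma2_within) or self.sigma2_within <= 0:
            raise ValueError("sigma2_within must be finite and > 0")

    @property
    def icc(self) -> float:
        total = self.sigma2_between + self.sigma2_within
        return self.sigma2_between / total


def simulate_cohort(
    n_flies: int,
    contexts: list[ContextModifier],
    components: VarianceComponents,
    seed: int,
    trait: str = "trait",
) -> pd.DataFrame:
    """Long-format cohort table: one row per fly x context.

    value = grand mean + fly intercept + sum(slope x factor code) + residual,
    where the fly intercept is N(0, sigma2_between), the residual
    N(0, sigma2_within), and a context's ``rank_disruption`` d replaces the
    intercept by sqrt(1-d)*intercept + sqrt(d)*fresh, keeping the marginal
    between-fly variance while degrading rank preservation.
    """
    if n_flies < 2:
        raise ValueError("need at least 2 flies")
    if not contexts:
        raise ValueError("need at least one context")
    rng = np.random.default_rng(seed)
    intercepts = rng.normal(0.0, np.sqrt(components.sigma2_between), n_flies)
    rows = []
    for ctx in contexts:
        codes = ctx.factor_codes()
        fixed = sum(
            slope * codes[name] for name, slope in components.fixed_effects.items()
        )
        d = ctx.rank_disruption
        fresh = rng.normal(0.0, np.sqrt(components.sigma2_between), n_flies)
        eff_intercepts = np.sqrt(1.0 - d) * intercepts + np.sqrt(d) * fresh
        resid = rng.normal(0.0, np.sqrt(components.sigma2_within), n_flies)
        values = components.grand_mean + eff_intercepts + fixed + resid
        for i in range(n_flies):
            rows.append(
                {
                    "fly": i,
                    "context": ctx.context_id,
                    **{k: codes[k] for k in FACTOR_COLUMNS},
                    "modality": ctx.modality,
                    "trait": trait,
                    "value": values[i],
                }
            )
    return pd.DataFrame(rows)


def _wrap180(deg):
    return (np.asarray(deg) + 180.0) % 360.0 - 180.0


def simulate_walk(
    profile: LatentFlyProfile,
    modifier: ContextModifier = ContextModifier(),
    arena_radius: float = 24.5,
    duration: float = 60.0,
    rate: float = 20.0,
    seed: int = 0,
    stripe_axis_deg: float = 0.0,
    mean_bout_s: float = 2.0,
) -> Trajectory:
    """Two-state correlated random walk in a disk, mm units.

    While walking, each step has length base_speed*speed_scale/rate and the
    movement direction evolves as previous + Gaussian noise + a fractional
    pull toward the nearer of the two opposite stimulus bearings (the
    two-stripe geometry, 180 deg apart) + a fractional pull toward the
    outward radial direction.  Walk/pause bouts form a two-state Markov
    chain whose stationary walking fraction is the profile's activity
    (shifted by the context); positions are reflected at the wall.  The
    ground-truth walk flag per frame is stored on the trajectory.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if arena_radius <= 0:
        raise ValueError("arena_radius must be positive")
    n = int(round(duration * rate))
    if n < 2:
        raise ValueError("need at least 2 frames (duration * rate >= 2)")
    rng = np.random.default_rng(seed)

    activity = float(np.clip(profile.activity + modifier.activity_shift, 0.0, 1.0))
    step = profile.base_speed * modifier.speed_scale / rate
    pull = min(profile.stripe_attraction * modifier.attraction_scale, 1.0)
    edge_pull = min(profile.edge_bias, 1.0)

    # two-state Markov chain with mean walking-bout length mean_bout_s and
    # stationary walking probability = activity
    p_stop = min(1.0, 1.0 / (mean_bout_s * rate))
    if activity <= 0.0:
        p_start = 0.0
        p_stop = 1.0
    elif activity >= 1.0:
        p_start = 1.0
        p_stop = 0.0
    else:
        p_start = min(1.0, activity * p_stop / (1.0 - activity))

    x = np.empty(n)
    y = np.empty(n)
    walking = np.empty(n, dtype=bool)
    # start somewhere inside the inner 70% of the arena
    r0 = arena_radius * 0.7 * np.sqrt(rng.uniform())
    a0 = rng.uniform(0.0, 360.0)
    x[0] = r0 * np.cos(np.radians(a0))
    y[0] = r0 * np.sin(np.radians(a0))
    walking[0] = rng.uniform() < activity
    theta = rng.uniform(0.0, 360.0)

    noise = rng.normal(0.0, profile.turn_noise, n)
    uni = rng.uniform(size=n)
    for i in range(1, n):
        if walking[i - 1]:
            walking[i] = uni[i] >= p_stop
        else:
            walking[i] = uni[i] < p_start
        if not walking[i]:
            x[i], y[i] = x[i - 1], y[i - 1]
            continue
        theta = theta + noise[i]
        if pull > 0.0:
            d1 = _wrap180(stripe_axis_deg - theta)
            d2 = _wrap180(stripe_axis_deg + 180.0 - theta)
            theta = theta + pull * (d1 if abs(d1) <= abs(d2) else d2)
        if edge_pull > 0.0:
            outward = np.degrees(np.arctan2(y[i - 1], x[i - 1]))
            theta = theta + edge_pull * _wrap180(outward - theta)
        nx = x[i - 1] + step * np.cos(np.radians(theta))
        ny = y[i - 1] + step * np.sin(np.radians(theta))
        r = np.hypot(nx, ny)
        if r > arena_radius:
            # reflect across the wall, radially
            nr = max(0.0, 2.0 * arena_radius - r)
            nx, ny = nx * nr / r, ny * nr / r
            theta = np.degrees(np.arctan2(ny - y[i - 1], nx - x[i - 1]))
        x[i], y[i] = nx, ny
    return Trajectory(
        roi_id=profile.fly_id,
        time=np.arange(n) / rate,
        x=x,
        y=y,
        detected=np.ones(n, dtype=bool),
        state=walking,
    )


def simulate_flight_headings(
    profile: LatentFlyProfile,
    modifier: ContextModifier = ContextModifier(modality="flight"),
    duration: float = 60.0,
    rate: float = 90.0,
    seed: int = 0,
    preferred_heading: float | None = None,
    mode: str = "fixation",
    rotation_deg_s: float = 120.0,
    pause_rate_hz: float = 0.0,
    mean_pause_s: float = 1.0,
) -> HeadingSeries:
    """Heading series for a tethered fly, degrees in [0, 360).

    In ``fixation`` mode the heading fluctuates around a fly-specific
    preferred axis (drawn uniformly if not given), mean-reverting with rate
    set by ``stripe_attraction`` and per-step noise ``turn_noise``; in
    ``optomotor`` mode the heading drifts at a constant ``rotation_deg_s``.
    Non-flying bouts start at rate ``pause_rate_hz`` with geometric
    durations of mean ``mean_pause_s``; the heading is held while paused.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if rate <= 0:
        raise ValueError("rate must be positive")
    n = int(round(duration * rate))
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    if preferred_heading is None:
        preferred_heading = float(rng.uniform(0.0, 360.0))

    flying = np.ones(n, dtype=bool)
    if pause_rate_hz > 0.0:
        p_pause = min(1.0, pause_rate_hz / rate)
        p_resume = min(1.0, 1.0 / (mean_pause_s * rate))
        state = True
        u = rng.uniform(size=n)
        for i in range(n):
            state = (u[i] >= p_pause) if state else (u[i] < p_resume)
            flying[i] = state

    heading = np.empty(n)
    if mode == "optomotor":
        heading[:] = preferred_heading + rotation_deg_s * np.arange(n) / rate
    elif mode == "fixation":
        lam = min(1.0, profile.stripe_attraction * modifier.attraction_scale)
        dev = 0.0
        noise = rng.normal(0.0, profile.turn_noise, n)
        for i in range(n):
            heading[i] = preferred_heading + dev
            if flying[i]:
                dev = (1.0 - lam) * dev + noise[i]
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    # hold heading during non-flying bouts
    for i in range(1, n):
        if not flying[i]:
            heading[i] = heading[i - 1]
    return HeadingSeries(
        time=np.arange(n) / rate,
        heading=heading % 360.0,
        flying=flying,
    )


# ---------------------------------------------------------------------------
# rendering


def _draw_body(
    canvas: np.ndarray,
    cx: float,
    cy: float,
    angle_deg: float,
    *,
    a: float = 4.0,
    b: float = 2.0,
    contrast: float = 170.0,
    taper: float = 0.0,
    supersample: int = 4,
) -> None:
    """Subtract a dark anti-aliased fly body at (cx, cy), image coordinates.

    The body is an ellipse with semi-axes (a, b) oriented ``angle_deg``
    counter-clockwise (math convention; image y runs down).  ``taper`` > 0
    narrows the half of the ellipse toward the heading (the head end), so
    the head carries less pixel mass than the abdomen.  Anti-aliasing by
    ``supersample`` x ``supersample`` coverage within each pixel.
    """
    h, w = canvas.shape
    rad = int(np.ceil(a + b)) + 2
    x0, x1 = int(np.floor(cx)) - rad, int(np.floor(cx)) + rad + 1
    y0, y1 = int(np.floor(cy)) - rad, int(np.floor(cy)) + rad + 1
    x0c, x1c = max(0, x0), min(w, x1)
    y0c, y1c = max(0, y0), min(h, y1)
    if x0c >= x1c or y0c >= y1c:
        return
    s = supersample
    off = (np.arange(s) + 0.5) / s - 0.5  # sub-pixel sample offsets
    t = np.radians(angle_deg)
    ct, st = np.cos(t), np.sin(t)
    gx = np.repeat(np.arange(x0c, x1c), s) + np.tile(off, x1c - x0c)  # (nx*s,)
    gy = np.repeat(np.arange(y0c, y1c), s) + np.tile(off, y1c - y0c)  # (ny*s,)
    GX, GY = np.meshgrid(gx, gy)  # (ny*s, nx*s)
    dx = GX - cx
    dy = -(GY - cy)
    xb = dx * ct + dy * st
    yb = -dx * st + dy * ct
    tt = np.clip(xb / a, -1.0, 1.0)
    b_eff = b * (1.0 + taper / 2.0 - taper * (tt + 1.0) / 2.0)  # head (t=+1) narrower
    inside = (xb / a) ** 2 + (yb / np.maximum(b_eff, 1e-9)) ** 2 <= 1.0
    cov = inside.reshape(y1c - y0c, s, x1c - x0c, s).mean(axis=(1, 3))
    canvas[y0c:y1c, x0c:x1c] -= contrast * cov


def _draw_ellipse(
    canvas: np.ndarray,
    cx: float,
    cy: float,
    a: float,
    b: float,
    angle_deg: float,
    contrast: float,
    supersample: int = 4,
) -> None:
    _draw_body(
        canvas, cx, cy, angle_deg, a=a, b=b, contrast=contrast, taper=0.0,
        supersample=supersample,
    )


def render_arena_frame(
    layout: ArenaLayout,
    frame_shape: tuple[int, int],
    arena_level: float = 200.0,
    surround_level: float = 20.0,
) -> np.ndarray:
    """Empty back-lit arenas: bright disks (or Y footprints) on dark surround."""
    h, w = frame_shape
    canvas = np.full((h, w), surround_level, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for roi in layout:
        d = np.sqrt((xx - roi.cx) ** 2 + (yy - roi.cy) ** 2)
        cov = np.clip(roi.radius_px + 0.5 - d, 0.0, 1.0)  # anti-aliased rim
        canvas += (arena_level - surround_level) * cov
    return canvas


def render_video(
    trajectories: list[Trajectory],
    layout: ArenaLayout,
    frame_shape: tuple[int, int],
    body_axes_px: tuple[float, float] = (4.0, 2.0),
    body_contrast: float = 170.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    hide: dict[int, tuple[int, int]] | None = None,
) -> np.ndarray:
    """Render one dark fly per roi per frame; returns a (n, h, w) uint8 stack.

    Trajectories are in arena mm coordinates and are mapped into the image
    through each roi's centre and mm-per-px scale.  The body ellipse is
    oriented along the local movement direction.  ``hide`` maps roi_id to a
    frame range [start, stop) during which that fly is not drawn (for
    testing the tracker's hold-on-loss behavior).
    """
    if len(trajectories) != len(layout):
        raise ValueError(
            f"{len(trajectories)} trajectories for {len(layout)} rois; need one per roi"
        )
    n_frames = len(trajectories[0])
    if any(len(t) != n_frames for t in trajectories):
        raise ValueError("all trajectories must have the same length")
    base = render_arena_frame(layout, frame_shape)
    rng = np.random.default_rng(seed)
    rois = list(layout)

    # precompute pixel positions and movement orientations
    px = np.empty((len(rois), n_frames))
    py = np.empty((len(rois), n_frames))
    ang = np.empty((len(rois), n_frames))
    for i, (traj, roi) in enumerate(zip(trajectories, rois)):
        px[i] = roi.cx + traj.x / roi.mm_per_px
        py[i] = roi.cy - traj.y / roi.mm_per_px
        dx = np.gradient(traj.x)
        dy = np.gradient(traj.y)
        a = np.degrees(np.arctan2(dy, dx))
        a[np.hypot(dx, dy) < 1e-9] = np.nan
        # carry last orientation over stationary stretches
        last = 0.0
        for j in range(n_frames):
            if np.isnan(a[j]):
                a[j] = last
            else:
                last = a[j]
        ang[i] = a

    frames = np.empty((n_frames, *frame_shape), dtype=np.uint8)
    a_ax, b_ax = body_axes_px
    for f in range(n_frames):
        canvas = base.copy()
        for i, roi in enumerate(rois):
            if hide and roi.id in hide:
                start, stop = hide[roi.id]
                if start <= f < stop:
                    continue
            _draw_body(
                canvas, px[i, f], py[i, f], ang[i, f],
                a=a_ax, b=b_ax, contrast=body_contrast,
            )
        if noise_sd > 0:
            canvas = canvas + rng.normal(0.0, noise_sd, canvas.shape)
        frames[f] = np.clip(canvas, 0, 255).astype(np.uint8)
    return frames


def render_flight_video(
    headings_deg: np.ndarray,
    frame_shape: tuple[int, int] = (120, 120),
    body_length_px: float = 60.0,
    background_level: float = 220.0,
    body_level: float = 10.0,
    wings_visible: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Close-up silhouette of a tethered fly at the given per-frame headings.

    The body is a tapered ellipse (head end narrower, pointing along the
    heading) centred in the frame, dark on a bright back-light.  Frames
    where ``wings_visible`` is true additionally carry two thin wing
    ellipses swept back from the body centre, as when a fly stops flying.
    """
    headings_deg = np.asarray(headings_deg, dtype=float)
    h, w = frame_shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    a = body_length_px / 2.0
    b = body_length_px / 6.0
    contrast = background_level - body_level
    rng = np.random.default_rng(seed)
    frames = np.empty((len(headings_deg), h, w), dtype=np.uint8)
    for f, hd in enumerate(headings_deg):
        canvas = np.full((h, w), background_level, dtype=float)
        _draw_body(canvas, cx, cy, hd, a=a, b=b, contrast=contrast, taper=0.6)
        if wings_visible is not None and wings_visible[f]:
            # wings are translucent and thin: dark enough to threshold at the
            # weak blur scale, washed out by the strong (body) blur
            for side in (+1.0, -1.0):
                wang = hd + 180.0 + side * 55.0  # swept back from the thorax
                wl = 0.45 * body_length_px
                wx = cx + wl * np.cos(np.radians(wang))
                wy = cy - wl * np.sin(np.radians(wang))
                _draw_ellipse(
                    canvas, wx, wy, wl, 0.08 * body_length_px, wang, 0.55 * contrast
                )
        if noise_sd > 0:
            canvas = canvas + rng.normal(0.0, noise_sd, canvas.shape)
        frames[f] = np.clip(canvas, 0, 255).astype(np.uint8)
    return frames
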