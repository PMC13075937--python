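"""Behavioral parameter suite for walking and flight data.

Walking trajectories (after the walking filter) yield exploration
(% of time walked, walking speed), attention (vector strength and angular
velocity of the movement directions, axial because the two stimulus stripes
sit 180 deg apart), and anxiety (centrophobicity, the fraction of time
spent in the outer ring beyond 80% of the arena radius).  Flight heading
series yield exploration (# of pauses, absolute angular velocity) and
attention (vector strength, signed angular velocity, median axial heading).

Angular statistics use the mean resultant vector: R = |mean of unit
vectors|, with angles doubled first for axial data so that opposite
headings count as the same axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flight import HeadingSeries
from .walking import FilteredTrajectory, Trajectory

#: radius fraction delimiting the arena's center region
CENTER_REGION_FRACTION = 0.8
#: quantile of nonzero bin counts that caps the heatmap color scale
HEATMAP_CEILING_QUANTILE = 0.95
#: minimum non-flying bout duration counted as a pause, s
PAUSE_MIN_DURATION_S = 0.2

WALK_PARAMETERS = (
    "percent_time_walked",
    "walking_speed",
    "vector_strength",
    "angular_velocity",
    "centrophobicity",
)
FLIGHT_PARAMETERS = (
    "n_pauses",
    "absolute_angular_velocity",
    "vector_strength",
    "angular_velocity",
    "median_heading_axial",
)


@dataclass
class BehaviorProfile:
    """Named parameter values for one fly in one context."""

    fly_id: int | str
    context_id: str
    modality: str  # "walk" | "flight"
    parameters: dict[str, float | None] = field(default_factory=dict)

    def is_mover(self) -> bool:
        if self.modality == "walk":
            return (self.parameters.get("percent_time_walked") or 0.0) > 0.0
        return self.parameters.get("_flew", 0.0) > 0.0


def percent_time_walked(filtered: FilteredTrajectory) -> float:
    """Share of frames (after the first) on which the position advanced, %."""
    n = len(filtered)
    if n < 2:
        raise ValueError("need at least 2 frames")
    return 100.0 * float(np.sum(filtered.updated[1:])) / (n - 1)


def walking_speed(filtered: FilteredTrajectory, rate: float) -> float | None:
    """Mean speed over walking (updated) frames only, mm/s; None if never walked.

    Averaging over walking frames keeps the estimate undiluted by pauses;
    a whole-recording average is ``np.sum(steps) * rate / (n - 1)`` if wanted.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    upd = np.flatnonzero(filtered.updated[1:]) + 1
    if len(upd) == 0:
        return None
    steps = np.hypot(
        filtered.x[upd] - filtered.x[upd - 1], filtered.y[upd] - filtered.y[upd - 1]
    )
    # each updated frame's step was traversed within one frame interval
    return float(np.mean(steps) * rate)


def vector_strength(angles_deg, axial: bool = False) -> float:
    """Mean resultant length of unit vectors at the given angles, in [0, 1].

    ``axial`` doubles the angles first so that directions 180 deg apart
    reinforce instead of cancelling (two-stripe geometry).
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise ValueError("need at least one angle")
    if axial:
        angles = 2.0 * angles
    z = np.exp(1j * np.radians(angles))
    return float(np.abs(z.mean()))


def angular_velocity(directions_deg, rate: float, mode: str = "signed") -> float:
    """Mean turning rate from a direction sequence, deg/s.

    Successive differences are mapped to the shortest arc (-180, 180];
    ``signed`` averages them (turning bias), ``absolute`` averages their
    magnitudes (total turning).
    """
    d = np.asarray(directions_deg, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 samples")
    diffs = np.diff(d)
    diffs = -((-diffs + 180.0) % 360.0 - 180.0)
    if mode == "signed":
        return float(np.mean(diffs) * rate)
    if mode == "absolute":
        return float(np.mean(np.abs(diffs)) * rate)
    raise ValueError(f"unknown mode: {mode!r}")


def median_heading_axial(headings_deg) -> float:
    """Circular median of headings folded to an axis, degrees in [0, 180).

    Headings are folded mod 180, doubled, the circular median taken on the
    doubled angles, and the result halved back.
    """
    h = np.asarray(headings_deg, dtype=float)
    if h.size == 0:
        raise ValueError("need at least one heading")
    doubled = np.radians((h % 180.0) * 2.0)
    # circular median: the angle minimising summed arc distances to the
    # samples; ties between sample minimisers resolve to their circular mean
    cands = np.unique(doubled)
    costs = np.array(
        [np.abs(np.angle(np.exp(1j * (doubled - c)))).sum() for c in cands]
    )
    winners = cands[costs <= costs.min() + 1e-9]
    med = np.angle(np.exp(1j * winners).mean())
    return float((np.degrees(med) / 2.0) % 180.0)


def centrophobicity(
    traj: Trajectory, arena_radius: float, center_fraction: float = CENTER_REGION_FRACTION
) -> float:
    """Fraction of frames outside the center region (edge-ring time), [0, 1].

    The center region is the disk of ``center_fraction`` (default 80%) of
    the arena radius; uniform occupancy gives 1 - 0.8^2 = 0.36.
    """
    if arena_radius <= 0:
        raise ValueError("arena_radius must be positive")
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    r = np.hypot(traj.x, traj.y)
    return float(np.mean(r > center_fraction * arena_radius))


def count_pauses(series: HeadingSeries, min_duration: float = PAUSE_MIN_DURATION_S) -> int:
    """Number of maximal non-flying runs lasting at least ``min_duration`` s."""
    if min_duration < 0:
        raise ValueError("min_duration must be >= 0")
    stopped = ~series.flying
    if not stopped.any():
        return 0
    dt = float(np.median(np.diff(series.time))) if len(series) > 1 else 0.0
    # run-length encode the stopped flag
    edges = np.flatnonzero(np.diff(stopped.astype(int)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [len(stopped)]])
    n = 0
    for s, e in zip(starts, ends):
        if stopped[s] and (e - s) * dt >= min_duration:
            n += 1
    return n


def occupancy_heatmap(traj: Trajectory, arena_radius: float, bins: int = 40):
    """2-D occupancy histogram over the arena bounding square + color ceiling.

    Returns ``(counts, (xedges, yedges), ceiling)`` where the ceiling is the
    95%-quantile of the *nonzero* bin counts — the value at which the color
    scale saturates so that a few hot bins do not flatten the rest.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    counts, xe, ye = np.histogram2d(
        traj.x, traj.y, bins=bins,
        range=[[-arena_radius, arena_radius], [-arena_radius, arena_radius]],
    )
    ceiling = heatmap_ceiling(counts)
    return counts, (xe, ye), ceiling


def heatmap_ceiling(counts: np.ndarray, quantile: float = HEATMAP_CEILING_QUANTILE) -> float:
    """Color ceiling: the given quantile of the nonzero bin counts."""
    nz = np.asarray(counts)[np.asarray(counts) > 0]
    if nz.size == 0:
        return 0.0
    return float(np.quantile(nz, quantile))


def _movement_directions(filtered: FilteredTrajectory) -> np.ndarray:
    """Directions (deg) of the updated steps, in temporal order."""
    upd = np.flatnonzero(filtered.updated[1:]) + 1
    anchors = np.concatenate([[0], upd])
    dx = filtered.x[anchors[1:]] - filtered.x[anchors[:-1]]
    dy = filtered.y[anchors[1:]] - filtered.y[anchors[:-1]]
    return np.degrees(np.arctan2(dy, dx))


def compute_profile(
    data: FilteredTrajectory | HeadingSeries,
    fly_id,
    context_id: str,
    modality: str,
    rate: float | None = None,
    arena_radius: float | None = None,
    pause_min_duration: float = PAUSE_MIN_DURATION_S,
) -> BehaviorProfile:
    """Fill the five modality-specific parameters for one recording.

    Walking attention angles are the movement directions of updated steps
    (evaluated axially); flight attention angles are the headings of flying
    frames.  Parameters that are undefined for the recording (e.g. speed of
    a fly that never walked) are recorded as missing (None), never as zero.
    """
    params: dict[str, float | None] = {}
    if modality == "walk":
        if not isinstance(data, FilteredTrajectory):
            raise TypeError("walk modality expects a FilteredTrajectory")
        if rate is None:
            rate = 1.0 / float(np.median(np.diff(data.time)))
        if arena_radius is None:
            raise ValueError("walk modality needs arena_radius")
        params["percent_time_walked"] = percent_time_walked(data)
        params["walking_speed"] = walking_speed(data, rate)
        dirs = _movement_directions(data)
        params["vector_strength"] = vector_strength(dirs, axial=True) if dirs.size else None
        params["angular_velocity"] = (
            angular_velocity(dirs, rate, mode="signed") if dirs.size >= 2 else None
        )
        params["centrophobicity"] = centrophobicity(data, arena_radius)
    elif modality == "flight":
        if not isinstance(data, HeadingSeries):
            raise TypeError("flight modality expects a HeadingSeries")
        if rate is None:
            rate = 1.0 / float(np.median(np.diff(data.time)))
        params["n_pauses"] = float(count_pauses(data, pause_min_duration))
        flew = data.flying
        heads = data.heading[flew]
        params["_flew"] = float(np.sum(flew))
        if heads.size:
            params["vector_strength"] = vector_strength(heads, axial=False)
            params["median_heading_axial"] = median_heading_axial(heads)
        else:
            params["vector_strength"] = None
            params["median_heading_axial"] = None
        if len(data.heading) >= 2:
            params["angular_velocity"] = angular_velocity(data.heading, rate, "signed")
            params["absolute_angular_velocity"] = angular_velocity(
                data.heading, rate, "absolute"
            )
        else:
            params["angular_velocity"] = None
            params["absolute_angular_velocity"] = None
    else:
        raise ValueError(f"unknown modality: {modality!r}")
    return BehaviorProfile(
        fly_id=fly_id, context_id=context_id, modality=modality, parameters=params
    )


def exclude_nonmovers(profiles: list[BehaviorProfile]):
    """Split profiles into (kept, excluded): flies that never moved are dropped.

    A walking fly that never produced an updated frame, or a tethered fly
    that never flew, carries no interpretable parameters.
    """
    kept = [p for p in profiles if p.is_mover()]
    excluded = [p for p in profiles if not p.is_mover()]
    return kept, excluded


def profiles_to_table(profiles: list[BehaviorProfile]) -> pd.DataFrame:
    """Wide table: one row per fly x context, one column per parameter."""
    rows = []
    for p in profiles:
        row = {"fly": p.fly_id, "context": p.context_id, "modality": p.modality}
        row.update({k: v for k, v in p.parameters.items() if not k.startswith("_")})
        rows.append(row)
    return pd.DataFrame(rows)
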