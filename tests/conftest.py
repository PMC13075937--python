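"""Shared fixtures: small layouts and rendered videos with known ground truth."""

import numpy as np
import pytest

from idiofly import arena, simulate


@pytest.fixture(scope="session")
def single_roi_layout():
    """One 49 mm arena of 50 px radius centred in a 120x120 frame."""
    roi = arena.Roi(
        id=0, shape="circle", cx=60.0, cy=60.0, radius_px=50.0, row=0, col=0,
        mm_per_px=arena.MULTI_ARENA_DIAMETER_MM / 100.0,
    )
    return arena.ArenaLayout(rois=[roi], arena_diameter_mm=arena.MULTI_ARENA_DIAMETER_MM)


def grid_layout(grid: int = 5, radius_px: float = 45.0, pitch_px: float = 100.0):
    mm_per_px = arena.MULTI_ARENA_DIAMETER_MM / (2 * radius_px)
    rois = [
        arena.Roi(
            id=r * grid + c, shape="circle",
            cx=pitch_px / 2 + c * pitch_px, cy=pitch_px / 2 + r * pitch_px,
            radius_px=radius_px, row=r, col=c, mm_per_px=mm_per_px,
        )
        for r in range(grid)
        for c in range(grid)
    ]
    return (
        arena.ArenaLayout(rois=rois, arena_diameter_mm=arena.MULTI_ARENA_DIAMETER_MM),
        (int(grid * pitch_px), int(grid * pitch_px)),
    )


@pytest.fixture(scope="session")
def walk_video(single_roi_layout):
    """A 20 s, 20 fps rendered walking fly plus its ground-truth trajectory."""
    profile = simulate.LatentFlyProfile(
        fly_id=0, base_speed=10.0, activity=0.7, turn_noise=25.0
    )
    traj = simulate.simulate_walk(
        profile, arena_radius=20.0, duration=20.0, rate=20.0, seed=11
    )
    frames = simulate.render_video([traj], single_roi_layout, (120, 120), seed=12)
    return frames, traj, single_roi_layout
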