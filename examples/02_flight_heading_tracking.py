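"""Track a tethered fly's 360-degree heading from silhouette video.

Renders a magneto-tethered fly rotating at the 120 deg/s optomotor
pre-test speed, then a fixation bout with a stop (wings visible), and runs
the two-scale segmentation + ellipse-fit + quadrant head-assignment
tracker on both.
"""

import numpy as np

from idiofly import flight, params, simulate

rate = flight.FLIGHT_TRACKING_RATE_HZ  # 90 fps

# --- optomotor pre-test: constant 120 deg/s rotation for 10 s
n = int(rate * 10)
truth = (flight.OPTOMOTOR_PRETEST_DEG_S * np.arange(n) / rate) % 360.0
frames = simulate.render_flight_video(truth, noise_sd=2.0, seed=0)
series = flight.track_flight(frames, rate=rate)
unwrapped = flight.unwrap_headings(series)
slope = (unwrapped[-1] - unwrapped[0]) / (series.time[-1] - series.time[0])
print(f"optomotor: recovered {slope:.2f} deg/s (stimulus 120.00 deg/s)")

# --- fixation with a 1 s flight stop: wings become visible when stopped
n = int(rate * 6)
fix = simulate.simulate_flight_headings(
    simulate.LatentFlyProfile(fly_id=0, stripe_attraction=0.3, turn_noise=4.0),
    duration=6.0, rate=rate, seed=3, preferred_heading=135.0,
)
stopped = np.zeros(n, bool)
stopped[180:270] = True  # 1 s stop bout
frames = simulate.render_flight_video(fix.heading, wings_visible=stopped, seed=4)
series = flight.track_flight(frames, rate=rate)

flying_heads = series.heading[series.flying]
print(f"fixation: vector strength {params.vector_strength(flying_heads):.3f}, "
      f"median axial heading {params.median_heading_axial(flying_heads):.1f} deg")
print(f"pauses detected: {params.count_pauses(series)} "
      f"(rendered: 1 stop bout of 1 s)")
print(
    "\nThe tracker resolves the 180-degree ellipse ambiguity by assigning the\n"
    "head to the body half with the smaller pixel sum; wing detection in the\n"
    "appendage mask marks non-flying frames."
)
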