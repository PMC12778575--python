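"""Detect turning bouts, classify pivots vs swerves, extract leg gestures.

Simulates a session with commanded turns of both signs, detects bouts as
peaks in the heavily smoothed rotational velocity bounded by 10 deg/s
crossings, canonicalizes left turns into right turns, classifies each bout
by its forward-velocity change, and reports the per-leg stride-length
changes at the rotational peak.
"""

import numpy as np

import flysteer as fs
from flysteer._smoothing import gaussian_smooth
from flysteer.kinematics import step_table

schedule = (
    fs.CommandedBout(onset=4.0, duration=0.5, direction="right", magnitude=100.0, forward_delta=-3.0),
    fs.CommandedBout(onset=9.0, duration=0.45, direction="left", magnitude=120.0, forward_delta=3.0),
    fs.CommandedBout(onset=14.0, duration=0.55, direction="right", magnitude=70.0, forward_delta=3.0),
)
cfg = fs.SimulationConfig(duration=20.0, seed=4, noise_sd_velocity=2.0, turn_schedule=schedule)
session = fs.simulate_walking(cfg)
v = session.velocities_true

forward_light = gaussian_smooth(v.forward, 0.1 * v.rate)
bouts = fs.detect_turning_bouts(v.rotational_heavy, v.rate, forward=forward_light)
print(f"{len(bouts)} bouts detected (3 commanded)")
for b in bouts:
    cat = fs.classify_pivot_swerve(b)
    print(
        f"  t={b.peak_time:5.2f} s  peak={b.peak_rot_velocity:+6.1f} deg/s  "
        f"dur={b.duration:.2f} s  {b.direction_original:<5s}  {cat}"
    )
print(
    "\nPivots slow down through the turn (forward velocity drops > 1 mm/s); "
    "swerves keep or gain speed."
)

_, steps, _ = fs.leg_analysis(session.tracked)
table = step_table(steps)
canon, steps_by = fs.canonicalize_left_turns(bouts, table)
ref = fs.not_turning_reference(table, v.time, v.rotational)
d = fs.step_deltas_at_peak(canon[0], steps_by[0], ref)
print("\nstride-length change at the first bout's peak (body lengths):")
for leg in ("R1", "R2", "R3", "L1", "L2", "L3"):
    side = "inside " if leg.startswith("R") else "outside"
    print(f"  {leg} ({side}): {d.d_stride_length[leg]:+.4f}")
print(
    "Inside legs shorten and outside legs lengthen by ~5% of a body length "
    "for a 100 deg/s turn - the generator's commanded leg gesture."
)
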