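"""Generate a synthetic walking session and extract step-cycle parameters.

Builds 20 s of noise-free tripod gait with one commanded right turn, runs
the kinematic pipeline (body axis -> body-frame leg tips -> step
segmentation -> per-step parameters), and compares the recovered steps with
the generator's ground truth.
"""

import numpy as np

import flysteer as fs
from flysteer.kinematics import LEGS, step_table

schedule = (
    fs.CommandedBout(onset=8.0, duration=0.5, direction="right", magnitude=100.0, forward_delta=-3.0),
)
cfg = fs.SimulationConfig(duration=20.0, seed=1, turn_schedule=schedule)
session = fs.simulate_walking(cfg)

frame, steps, continuum = fs.leg_analysis(session.tracked)
table = step_table(steps)

print(f"tracked {session.tracked.n_frames} frames at {cfg.frame_rate_legs:.0f} Hz")
for leg in LEGS:
    got, want = len(steps[leg]), len(session.ground_truth["steps"][leg])
    print(f"  {leg}: {got} steps detected ({want} ground truth)")

mean_stride = table.groupby("leg")["stride_length"].mean()
print("\nmean stride length per leg (body lengths):")
print(mean_stride.round(4).to_string())
print(
    "\nAll legs average ~{:.2f} body lengths per stride - the generator's base "
    "stride - because the single 0.5-s turn barely moves the session mean.".format(
        cfg.base_stride_length
    )
)

errs = [
    abs(st.stride_length - g[3])
    for leg in LEGS
    for st, g in zip(steps[leg], session.ground_truth["steps"][leg])
]
print(
    f"worst per-step stride-length error vs ground truth: {max(errs):.4f} body lengths "
    "(sub-frame extremum localization)"
)
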