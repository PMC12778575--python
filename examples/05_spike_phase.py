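"""Stride-phase spike locking: profile, preferred phase and depth.

Computes the common stride phase of all six legs (aligned to the right
middle leg), generates spikes whose intensity is locked to the phase read
100 ms before each spike (preferred phase 90 deg, depth 15 spikes/s), and
recovers the locking from the occupancy-normalized 72-bin spike-phase
histogram.
"""

import numpy as np

import flysteer as fs

session = fs.simulate_walking(fs.SimulationConfig(duration=120.0, seed=5))
_, _, continuum = fs.leg_analysis(session.tracked)
phases = {leg: continuum[leg].phase_deg for leg in continuum}
common, excluded = fs.common_stride_phase(phases, reference_leg="R2")
t = session.tracked.time
walking = np.isfinite(common)

rate = fs.phase_locked_rate(common, t, baseline=20.0, depth=15.0, preferred_deg=90.0, offset=0.1)
spikes = fs.simulate_spike_train(rate, seed=1)
profile = fs.spike_phase_profile(spikes.spike_times, common, t, walking, offset=0.1, n_bins=72)
depth, pref = fs.phase_modulation_depth(profile)

print(f"{len(spikes)} spikes over {session.config.duration:.0f} s of walking")
print(f"recovered preferred phase: {pref:6.1f} deg (true 90)")
print(f"recovered modulation depth: {depth:5.1f} spikes/s (true 15; the 2-ms")
print("  point-process dead time compresses the realized modulation by ~7%)")

flat = fs.RateTrace(times=t, rate=np.full_like(t, 20.0))
spikes0 = fs.simulate_spike_train(flat, seed=2)
profile0 = fs.spike_phase_profile(spikes0.spike_times, common, t, walking, offset=0.1, n_bins=72)
depth0, _ = fs.phase_modulation_depth(profile0)
print(f"unlocked control depth:     {depth0:5.1f} spikes/s (chance level)")
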