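# flysteer

Leg-kinematic and neural-behavioral analysis of steering in walking
*Drosophila*.

When a walking fly turns, it does not use a dedicated "turning leg" — it
subtly reshapes its ongoing stride cycle: the three legs on the outside of
the turn lengthen their strides, the three inside legs shorten theirs (by a
few percent of body length, repeated at the ~10 Hz stride rhythm), and the
front legs redirect their power strokes. Descending neurons (DNs) that
carry steering commands from the brain modulate their spike rate ~100–200 ms
*before* the resulting change in rotational velocity, and some lock their
spiking to the stride cycle. `flysteer` is a tested, reusable implementation
of the analysis chain needed to quantify all of this:

- **kinematics** — body-axis fitting (total least squares through the body
  landmarks), body-frame leg-tip coordinates in units of body length,
  outlier removal, step segmentation into posterior→anterior→posterior
  cycles, per-step AEP/PEP/stride-length/step-direction/swing–stance
  parameters, continuous (spline-through-extrema) stride estimates, and a
  0–360° stride-cycle phase;
- **velocity** — Gaussian-smoothed rotational/forward/lateral velocity and
  acceleration from spherical-treadmill (fictive) or freely-walking
  tracking, plus walking-bout detection with a 200-ms minimum-bout merge;
- **bouts** — turning-bout detection (peaks in heavily smoothed rotational
  velocity bounded by 10 °/s crossings, 0.3–0.7 s duration filter),
  left-turn canonicalization, pivot/swerve classification (forward velocity
  drops or rises by > 1 mm/s from bout start to rotational peak), per-leg
  step-parameter deltas at the turn peak, and bout-triggered stride-length
  time courses with FWHM;
- **neural** — spike detection from dV/dt threshold crossings with 2-ms
  refractory exclusion, instantaneous rate as inverse interspike interval,
  rate normalization, ratiometric ΔF/F with double-exponential bleach
  correction, and bilateral (right−left / right+left) signals;
- **filters** — first-order Wiener kernels between neural signals and
  behavior, in both the spectral-ratio form
  `F(ω) = I*(ω)R(ω) / (I*(ω)I(ω) + ε)` with the soft low-pass
  `c(ω) = e^{−(|ω|−f_cut)/f_τ}` (calcium: f_cut = 4 Hz, f_τ = 1 Hz) and the
  correlation-deconvolution form on a ±1 s, 1-ms lag grid (spikes:
  f_cut = 2 Hz, f_τ = 0.5 Hz), plus autocorrelation FWHM. Negative lags
  mean the neural signal precedes behavior;
- **tuning** — binned tuning curves with a fixed 100-ms neural-to-behavior
  offset, turning/non-turning splits, acceleration/deceleration
  conditioning, common stride phase across legs, and occupancy-normalized
  spike-phase profiles (72 bins);
- **synthetic** — a walking-fly generator (tripod gait, commanded turning
  bouts, spike trains whose rate leads rotational velocity by a known lag,
  calcium with bleach) with exact ground truth, so every stage above is
  testable without real recordings.

The package is a library: import it from Python. The `examples/` directory
holds one narrative script per capability.

## Worked example

```bash
python examples/02_turning_bouts.py
```

prints (abbreviated):

```
3 bouts detected (3 commanded)
  t= 4.31 s  peak= +98.3 deg/s  dur=0.51 s  right  pivot
  t= 9.28 s  peak=-117.6 deg/s  dur=0.46 s  left   swerve
  t=14.36 s  peak= +69.3 deg/s  dur=0.56 s  right  swerve

stride-length change at the first bout's peak (body lengths):
  R1 (inside ): -0.0459
  R2 (inside ): -0.0465
  ...
  L1 (outside): +0.0465
```

Each commanded turn is recovered with its peak rotational velocity and
duration; the bout that slowed the fly by more than 1 mm/s is a *pivot*,
the ones that sped it up are *swerves*; and at the rotational peak the
inside legs' strides are ~0.05 body lengths shorter than the not-turning
reference while the outside legs' are correspondingly longer — the
lateralized leg gesture that produces the turn.

`examples/04_wiener_filters.py` shows both Wiener estimators recovering the
generator's 100-ms neural-to-behavior latency as a filter peak at −0.100 s,
and `examples/05_spike_phase.py` recovers stride-phase locking (preferred
phase 90°, depth 15 spikes/s) from the occupancy-normalized spike-phase
histogram.

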