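# Methods

This note documents the models, conventions and numerical choices behind
`flysteer`, and what the synthetic-data experiments do and do not show.

## The synthetic walking fly

The generator (`flysteer.synthetic`) produces everything the analysis chain
consumes, with exact ground truth.

**Gait.** Six leg tips oscillate along the body's anterior–posterior (AP)
axis in a tripod pattern: L1/R2/L3 move in phase, R1/L2/R3 in anti-phase, at
a nominal stride frequency of 10 Hz. Each cycle is a piecewise-linear
sawtooth — a fast forward swing occupying `swing_fraction` (default 0.4) of
the cycle, then a slow backward stance — built by linear interpolation
between explicit extremum knots. Extrema are therefore exactly countable,
which is what lets step-segmentation tests demand exact step counts. The
default base stride is 0.4 body lengths (a fly walking ~12 mm/s with a
2.5-mm body takes ~1-mm strides); AP centers place front/middle/hind legs at
+0.25/0/−0.25 body lengths. A global phase offset of 0.25 cycles keeps
extremum knots off both the frame grid and the session edges, so discrete
sampling at 250 Hz localizes every extremum to within one frame.

**Steering.** A commanded bout is a raised-cosine turn command. It
multiplicatively shortens the stride amplitude of the three inside legs
(gain 0.5 per unit command) and lengthens the three outside legs (gain 0.5),
and rotational velocity is `rot_gain` × the relative left−right stride
asymmetry, directed toward the shorter-stride side (a fly pivots toward the
side taking smaller steps). With `rot_gain = 400 °/s` per unit asymmetry, a
100 °/s bout corresponds to ±0.05 body lengths of stride modulation — the
few-percent-of-body-length gesture scale observed in walking flies. The
bout's `duration` parameter is the target time between the 10 °/s bout
boundaries; the envelope support is widened analytically
(`D = duration / (1 − arccos(1 − 2·10/magnitude)/π)`) so the realized bout
passes the downstream 0.3–0.7 s duration filter at its commanded duration.
The forward-velocity envelope is scaled so the realized start-to-peak change
equals `forward_delta` exactly.

**Neural coupling.** Spike rate is
`baseline + gain · (G_σ ⋆ rot)(t + L)`: a Gaussian-smoothed copy of the
*future* rotational velocity, so rate leads behavior by the lag `L`
(default 100 ms, σ = 50 ms). Spikes are drawn by thinning an inhomogeneous
Poisson process with a 2-ms dead time, so the downstream refractory
exclusion is a no-op on clean data. Calcium is the rate convolved with a
difference of exponentials (rise 0.2 s, decay 1.5 s — jGCaMP7s-like
kinetics), multiplied by a double-exponential bleach envelope (τ = 60 s and
600 s), with a co-bleached constant red reference channel.

**Noise and determinism.** The generator defaults to noise-free output;
keypoint jitter, velocity noise and fluorescence noise are explicit
per-experiment parameters. All randomness derives from one session seed
fanned out to named substreams (position, velocity, spikes, calcium), so
identical configs reproduce bit-identical sessions.

**What the generator does not emulate:** tracking dropouts and identity
swaps, gait transitions (tetrapod/wave), speed-dependent stride frequency,
ball inertia, correlated sensor noise, motion artifacts in imaging, bursty
or adapting spike statistics. Passing tests demonstrate that the *analysis*
is correct and well-calibrated on data satisfying its assumptions, not that
real recordings meet those assumptions.

## Kinematic conventions

- Body axis per frame by total least squares (closed-form 2×2 PCA) through
  the mode's landmark set; head and abdomen projected onto the axis define
  body length; AP is positive toward the head, ML positive to the fly's
  right; leg positions are in units of body length.
- Outlier removal: a sample is replaced by its 5-frame running median when
  it deviates from it by more than 50% of the range of median-filtered
  values in a centered 500-frame window (windows truncate at edges; a zero
  local range makes any nonzero deviation an outlier, so constant traces
  pass through except true spikes).
- Step segmentation: alternating AP extrema found with a prominence
  threshold (default 0.02 body lengths) and a minimum half-step duration
  (default 10 ms), both configurable; each (min, max, min) triplet is one
  step; partial edge cycles are discarded. Frame indices are 0-based and
  step intervals half-open.
- Step direction: angle of the AEP→PEP (power-stroke) vector measured from
  straight-backward, signed positive when the PEP lands laterally away from
  the midline on that leg's own side. This side-signed convention makes
  left/right mirroring a pure label swap (direction values are already
  mirror-invariant), which is why canonicalizing left turns inverts
  rotational velocity and swaps leg labels but leaves direction values
  untouched.
- Swing/stance: free mode labels the half step with the larger mean
  world-frame leg-tip speed as swing; tethered mode labels the shorter half
  step as swing (swing is always briefer than stance). Ties label the first
  half swing and are flagged.
- Continuous stride estimates: shape-preserving (PCHIP) cubic interpolation
  through the AP maxima (continuous AEP) and minima (continuous PEP); the
  interpolant passes exactly through its knots, so continuous estimates
  agree with per-step values at the extrema by construction. Valid only
  between the first and last knots of both sides.
- Phase: 0° at swing onset, 180° at the swing/stance transition, 360° at
  stance end, linear in AP position within each half step (AP clamped to
  the anchor range if non-monotonic), stored mod 360.

## Velocity processing

All smoothing is a truncated-Gaussian moving average parameterized by its
full window; σ = window/5, kernel truncated at ±window/2 and renormalized,
edges renormalized over available samples (no padding). These operators are
linear, preserve constants exactly, and pass ramps unchanged in the
interior. Fictive processing: zero-phase 4th-order Butterworth low-pass at
40 Hz (zero phase protects latency estimates), linear resample to 1 kHz,
200-ms position smooth, derivative, sign conventions (rotational = −yaw′,
forward = −pitch′, lateral = −roll′), 100-ms velocity smooth. Free-walking
processing: 180°-disambiguation of the ellipse orientation against the
leg-tracking heading, 10-frame position/heading smooth, 15-frame velocity
smooth, and a 50-frame heavy variant of rotational velocity used only for
turning-bout detection. Acceleration: 250-ms smooth → derivative → 250-ms
smooth. Walking bouts: threshold on total speed (optionally also middle-leg
speed), then bouts shorter than 200 ms are flipped into their prior bout,
scanning left to right from the second bout; a too-short first bout merges
into its successor only as the final fallback. This ordering reproduces the
defining property that alternating short segments collapse to the first
segment's label.

## Turning bouts

Peaks above `min_peak` (default 20 °/s, matching the lowest analyzed
rotational-velocity bin) are found separately in the heavy-smoothed trace
and its negation, with a 0.3-s minimum peak separation; bout boundaries are
the nearest sub-sample 10 °/s crossings (linear interpolation); bouts
outside 0.3–0.7 s are dropped; of two bouts sharing an epoch the larger
peak wins. Forward velocity at the bout start and rotational peak is read
from the lightly smoothed forward trace; Δ < −1 mm/s ⇒ pivot, Δ > +1 mm/s ⇒
swerve, otherwise neither. Step deltas at the peak are taken from the step
whose interval covers the peak time, against a not-turning reference (steps
whose mid-time rotational speed is below 10 °/s); step-direction deltas use
circular arithmetic. Bout-triggered stride time courses are min–max
normalized per bout (zero-range snippets are skipped and counted); the FWHM
is the contiguous time above half of the maximum found within ±0.2 s of the
rotational peak.

## Neural preprocessing

Spikes are upward threshold crossings of the central-difference dV/dt;
crossings under 2 ms after the prior accepted crossing are excluded.
Instantaneous rate is 1/ISI over each interspike interval, zero outside the
spiking span (configurable to hold). Normalized rate subtracts the
not-walking mean and divides by the 95th percentile of the residual
distribution. ΔF/F: each background-subtracted channel is fit with
`a1·e^{−t/τ1} + a2·e^{−t/τ2}` (no offset by default; an offset term is an
option), deterministically initialized from two log-linear segment fits,
followed by up to two trimmed refits that exclude samples whose residual
exceeds 2.5 robust (MAD-based) standard deviations — so brief transients
riding on the bleach envelope do not bias F0. The ratiometric signal is
`(G/G0)/(R/R0) − 1`.

## Wiener kernels

Both estimators remove means first and apply the same soft spectral
low-pass `c(ω)` (unity below f_cut, `e^{−(|ω|−f_cut)/f_τ}` above, applied
symmetrically in ω so the output is real). The spectral-ratio variant
regularizes the denominator with ε = 10⁻⁶ × mean input power. The
correlation variant resamples both series to the 1-ms lag grid, computes
lagged correlations over ±1 s, and divides their Fourier transforms. Two
numerical choices matter here:

- **Correlogram normalization.** Per-lag ("unbiased") normalization makes
  the truncated autocorrelation spectrum indefinite and measurably biases
  the deconvolved peak (up to ~6 ms on 120-s sessions). The default is the
  biased (Bartlett, divide-by-n) correlogram: the implicit taper cancels in
  the numerator/denominator ratio and the denominator stays positive
  semidefinite; lag recovery on noise-free sessions is then exact at the
  1-ms grid. Correlation *values* are shrunk by 1 − |u|/n (< 1% for ±1 s on
  minutes of data), which is negligible for the 0.5-threshold
  autocorrelation FWHM at the session lengths used.
- **Units.** Pearson normalization leaves a σx/σy factor in the ratio; it
  is undone so filter values are response-units per input-unit, scaled as a
  density (per second) in both variants.

Lags are stored so negative lags always mean the input (neural signal)
precedes the response. `peak_time` is the lag of the global maximum, ties
broken toward smaller |lag|; a filter is flagged invalid when its maximum
sits within the outer 5% of lags or fails to exceed the edge values by 10%
of the range (the "no defined peak" exclusion, made operational).

## Tuning and phase analyses

Tuning curves bin the behavioral variable into equal-width bins spanning
its observed range, pair it with the neural series a fixed 100 ms earlier
(nearest-sample shift on the common grid), exclude bins under the minimum
count, and report the Pearson r of the same masked, lagged pairs.
Turning/not-turning splits use a 25 °/s rotational-speed threshold with ≥
assigned to turning. The "forward-stepping" mask requires the continuous
step direction of all four middle/hind legs within ±90° of straight
backward. Common stride phase aligns each leg to a reference leg by the
circular mean of its phase offset, then takes the per-frame circular mean.
Spike-phase profiles assign each walking-epoch spike to one of 72 bins by
the phase 100 ms before the spike, divide counts by occupancy (walking time
per bin, read with the same offset), and subtract the occupancy-weighted
mean rate — which makes the occupancy-weighted modulation sum exactly zero.
The modulation depth/preferred phase summary is an occupancy-weighted
least-squares fit of `a0 + d·cos(θ − θ0)`: unlike a plain harmonic
projection, the regression stays exact when the occupied phase support is
discrete or nonuniform, as it is for a perfectly regular gait sampled at a
commensurate frame rate.

## Validation experiments and problem sizes

`flysteer.validation` (used by both the test suite and
`scripts/acceptance.py`) sizes its experiments to run in a few minutes on
one core: a 60-s, 250-Hz noise-free session for step exactness; 20 sessions
× 6 commanded bouts (peaks 50–150 °/s, durations 0.4–0.6 s, forward deltas
±3 mm/s, 2 °/s / 2 mm/s velocity noise) for bout detection; 20 × 120-s
sessions per lag L ∈ {50, 100, 150, 200} ms for filter recovery, with the
generator's rate trace as the filter input (rates re-derived from sampled
spike trains carry Poisson jitter of tens of ms on the broad band-limited
filter peak — an intrinsic limit, not an estimator defect) and a
least-squares FIR oracle on 10 s of white noise; one 120-s session for
phase locking (baseline 20 spikes/s, depth 15, preferred phase 90°); and a
300-s two-channel trace for ΔF/F. Filter-recovery success is peak
localization within one step of the coarser of the estimator grid and the
generator's velocity grid (10 ms for the 100-Hz spectral variant, 4 ms for
the correlation variant on 250-Hz ground truth).

## Known limitations

- The phase-locking depth recovered from spike trains is ~7–13% below the
  commanded intensity modulation: the 2-ms dead time compresses high-rate
  epochs, and nearest-frame phase reads add jitter. This is a property of
  the point process, reported as such.
- The xcorr Wiener variant's exactness depends on signals decorrelating
  within the ±1 s window; stimuli spaced closer than ~2 s re-introduce
  truncation leakage.
- The double-exponential bleach fit assumes transients are sparse (the
  trimmed refit needs a majority of clean samples) and the envelope truly
  double-exponential; τ recovery is tested to 10% under those conditions.
- The step-direction sign convention is internally consistent (mirror
  symmetry is exact) but cannot be checked against external conventions
  without shared data; only the mirroring behavior is asserted.
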