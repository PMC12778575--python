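"""Synthetic walking-fly sessions with known ground truth.

Generates everything the analysis pipeline consumes - tracked leg/body
keypoints, body-velocity traces, spike trains and two-channel calcium
fluorescence - from a small set of interpretable parameters, so every
downstream stage can be tested against exact ground truth.

The gait model is a hexapod tripod: the two tripods (L1, R2, L3 and R1, L2,
R3) oscillate in anti-phase at the stride frequency. Each leg tip's
anterior-posterior (AP) position is a piecewise-linear sawtooth per cycle -
a fast forward swing occupying ``swing_fraction`` of the cycle followed by a
slow backward stance - so step extrema are exactly countable. Steering is
expressed the way walking flies express it: a turn command multiplicatively
shortens the stride amplitude of the three inside legs and lengthens the
three outside legs (modulations of a few percent of body length at ~10 Hz),
and the body's rotational velocity is proportional to the left-right stride
asymmetry, directed toward the shorter-stride side. Spike rate is a baseline
plus a gain times the (smoothed) rotational velocity read ``neural_lag``
seconds in the future, so neural activity leads behavior; calcium is the
rate passed through a difference-of-exponentials indicator kernel under a
double-exponential bleach envelope with a co-bleached red reference.

All randomness derives from one session seed fanned out to named substreams
(position, velocity, spikes, calcium), so identical configs reproduce
bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._smoothing import gaussian_smooth
from .kinematics import LEGS, TrackedSession
from .neural import RateTrace, SpikeTrain, FluorescenceTrace
from .velocity import VelocityTraces
from .filters import LinearFilter

__all__ = [
    "CommandedBout",
    "SimulationConfig",
    "SyntheticSession",
    "simulate_walking",
    "simulate_spike_train",
    "phase_locked_rate",
    "envelope_support",
]

_TRIPOD_A = ("L1", "R2", "L3")          # in phase with each other
_AP_CENTER = {"1": 0.25, "2": 0.0, "3": -0.25}       # body lengths
_ML_CENTER = {"1": 0.28, "2": 0.33, "3": 0.30}


@dataclass
class CommandedBout:
    """One commanded turning bout.

    ``duration`` is the target realized bout duration - the time the
    rotational velocity spends above the 10 deg/s bout boundary - and the
    raised-cosine command envelope is widened analytically so the boundary
    crossings land that far apart. ``forward_delta`` is the change in forward
    velocity at the bout peak (negative = pivot-like, positive =
    swerve-like).
    """

    onset: float                 # s, envelope start
    duration: float              # s, target time between the 10 deg/s crossings
    direction: str               # 'left' or 'right'
    magnitude: float             # deg/s, target peak rotational velocity
    forward_delta: float = 0.0   # mm/s at the bout peak

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("bout duration must be positive")
        if self.direction not in ("left", "right"):
            raise ValueError("direction must be 'left' or 'right'")
        if self.magnitude <= 10.0:
            raise ValueError("bout magnitude must exceed the 10 deg/s bout boundary")


def envelope_support(bout: CommandedBout, boundary: float = 10.0) -> float:
    """Raised-cosine support width that realizes the bout's target duration.

    For a raised-cosine bump of height ``magnitude`` the rotational velocity
    crosses ``boundary`` at a phase ``phi = arccos(1 - 2 boundary/magnitude)``
    into the envelope, so the crossings are ``(1 - phi/pi)`` of the support
    apart; the support is the target duration divided by that fraction.
    """
    r = boundary / bout.magnitude
    phi = np.arccos(1.0 - 2.0 * r)
    return float(bout.duration / (1.0 - phi / np.pi))


@dataclass
class SimulationConfig:
    duration: float = 60.0               # s of walking
    rest_duration: float = 0.0           # s of stationary rest prepended
    frame_rate_legs: float = 250.0       # Hz, camera frame rate
    rate_velocity: float = 250.0         # Hz of the body-velocity traces
    rate_calcium: float = 20.0           # Hz of the fluorescence traces
    stride_frequency: float = 10.0       # Hz
    base_stride_length: float = 0.4      # body lengths
    body_length: float = 2.5             # mm
    swing_fraction: float = 0.4          # of the cycle; < 0.5 (swing shorter than stance)
    phase_offset: float = 0.25           # cycles; global gait phase at t = rest_duration
    turn_schedule: tuple = ()            # CommandedBout instances
    gesture_gain_inside: float = 0.5     # fractional inside-leg shortening per unit command
    gesture_gain_outside: float = 0.5    # outside-leg lengthening per unit command
    rot_gain: float = 400.0              # deg/s per unit (left-right)/base stride asymmetry
    rot_smooth_sigma: float = 0.02       # s, Gaussian linking asymmetry to rotational velocity
    forward_base: float = 12.0           # mm/s cruising forward velocity
    neural_baseline: float = 30.0        # spikes/s during walking
    neural_rest_rate: float = 1.0        # spikes/s when not walking
    neural_gain: float = 0.2             # spikes/s per deg/s of (future) rotational velocity
    neural_lag: float = 0.1              # s by which spike rate leads rotational velocity
    neural_kernel_sigma: float = 0.05    # s, temporal spread of the rate->behavior coupling
    noise_sd_position: float = 0.0       # body lengths, keypoint jitter
    noise_sd_velocity: float = 0.0       # deg/s (rotational) and mm/s (translational)
    calcium_tau_rise: float = 0.2        # s
    calcium_tau_decay: float = 1.5       # s
    calcium_gain: float = 0.01           # dF/F units per (spikes/s x s) of indicator drive
    bleach_taus: tuple = (60.0, 600.0)   # s
    bleach_amps: tuple = (0.3, 0.7)      # fractions, sum 1
    baseline_fluorescence: float = 100.0
    noise_sd_fluorescence: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.swing_fraction < 0.5):
            raise ValueError("swing_fraction must lie in (0, 0.5): swing is shorter than stance")
        for name in ("duration", "frame_rate_legs", "rate_velocity", "rate_calcium",
                     "stride_frequency", "base_stride_length", "body_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.duration < 1.0 / self.stride_frequency:
            raise ValueError("duration must cover at least one stride")
        self.turn_schedule = tuple(self.turn_schedule)
        spans = sorted(
            (b.onset, b.onset + envelope_support(b)) for b in self.turn_schedule
        )
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("commanded bouts overlap (including their envelope supports)")

    @property
    def total_duration(self) -> float:
        return self.rest_duration + self.duration

    @property
    def neural_kernel(self) -> LinearFilter:
        """Ground-truth rate->rotational-velocity coupling filter.

        A Gaussian bump of width ``neural_kernel_sigma`` centered at
        ``-neural_lag`` (negative lag = the neural signal precedes behavior).
        """
        dt = 1.0 / self.rate_velocity
        half = self.neural_lag + 4 * self.neural_kernel_sigma
        lags = np.arange(-half, half + 0.5 * dt, dt)
        vals = np.exp(-0.5 * ((lags + self.neural_lag) / self.neural_kernel_sigma) ** 2)
        return LinearFilter(lags=lags, values=vals / self.neural_gain if self.neural_gain else vals)


@dataclass
class SyntheticSession:
    config: SimulationConfig
    tracked: TrackedSession
    velocities_true: VelocityTraces
    rate_true: RateTrace
    spikes: SpikeTrain
    calcium_green: FluorescenceTrace
    calcium_red: FluorescenceTrace
    ground_truth: dict


def _command_trace(cfg: SimulationConfig, t: np.ndarray) -> np.ndarray:
    """Signed, dimensionless turn command (positive = rightward)."""
    kappa = np.zeros_like(t)
    denom = cfg.rot_gain * (cfg.gesture_gain_inside + cfg.gesture_gain_outside)
    for b in cfg.turn_schedule:
        D = envelope_support(b)
        inside = (t >= b.onset) & (t <= b.onset + D)
        env = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[inside] - b.onset) / D))
        sign = 1.0 if b.direction == "right" else -1.0
        kappa[inside] += sign * (b.magnitude / denom) * env
    return kappa


def _amplitude_envelopes(cfg: SimulationConfig, kappa: np.ndarray) -> dict:
    """Per-leg stride-amplitude envelopes (body lengths)."""
    pos = np.maximum(kappa, 0.0)     # rightward command
    neg = np.maximum(-kappa, 0.0)    # leftward command
    g_in, g_out = cfg.gesture_gain_inside, cfg.gesture_gain_outside
    right = cfg.base_stride_length * (1.0 - g_in * pos + g_out * neg)
    left = cfg.base_stride_length * (1.0 + g_out * pos - g_in * neg)
    return {leg: (right if leg.startswith("R") else left) for leg in LEGS}


def _leg_trajectory(cfg, leg, t_legs, t_vel, amp_env):
    """Piecewise-linear sawtooth AP trajectory + ground-truth step list."""
    T = 1.0 / cfg.stride_frequency
    phi0 = cfg.phase_offset + (0.0 if leg in _TRIPOD_A else 0.5)
    t0 = cfg.rest_duration
    t_end = t_legs[-1]
    n_cycles = int(np.ceil((t_end - t0) / T)) + 2
    # with no rest period, extend one cycle before t=0 so the first
    # in-range posterior extremum is a genuine local minimum
    n_first = -1 if cfg.rest_duration == 0 else 0
    pep_t = t0 + (np.arange(n_first, n_cycles) + phi0) * T
    aep_t = pep_t + cfg.swing_fraction * T
    knots_t = np.sort(np.concatenate([pep_t, aep_t]))
    knots_t = knots_t[knots_t <= t_end + T]
    amp = np.interp(knots_t, t_vel, amp_env)
    center = _AP_CENTER[leg[1]]
    is_aep = np.isin(knots_t, aep_t)
    knots_ap = np.where(is_aep, center + amp / 2.0, center - amp / 2.0)
    ap = np.interp(t_legs, knots_t, knots_ap)

    # ground truth: complete (pep, aep, pep) cycles whose extrema are interior
    dt = t_legs[1] - t_legs[0]
    interior = lambda x: (x > t_legs[0] + dt) & (x < t_end - dt)
    steps = []
    for i in range(len(pep_t) - 1):
        p0, a0, p1 = pep_t[i], aep_t[i], pep_t[i + 1]
        if i == 0 and n_first == 0:
            continue  # no descent into the first extremum after a rest period
        if interior(p0) and interior(a0) and interior(p1):
            s = 0.5 * (np.interp(a0, t_vel, amp_env) + np.interp(p1, t_vel, amp_env))
            steps.append((float(p0), float(a0), float(p1), float(s)))
    return ap, steps


def simulate_walking(config: SimulationConfig) -> SyntheticSession:
    """Generate one synthetic walking session from a configuration.

    Returns a :class:`SyntheticSession` whose ``ground_truth`` dict records,
    per leg, the realized step times and stride lengths, plus each bout's
    realized peak rotational velocity and timing, the noise-free velocity
    traces, the true spike-rate trace and the leg-asymmetry command - enough
    to recompute every expected downstream estimate.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_pos, rng_vel, rng_spk, rng_ca = (np.random.default_rng(s) for s in ss.spawn(4))

    total = cfg.total_duration
    t_legs = np.arange(0.0, total, 1.0 / cfg.frame_rate_legs)
    t_vel = np.arange(0.0, total, 1.0 / cfg.rate_velocity)
    walking = t_vel >= cfg.rest_duration

    for b in cfg.turn_schedule:
        if b.onset < cfg.rest_duration:
            raise ValueError("commanded bout starts during the rest period")
        if b.onset + envelope_support(b) > total:
            raise ValueError("commanded bout extends past the session end")

    kappa = _command_trace(cfg, t_vel)
    amp = _amplitude_envelopes(cfg, kappa)

    # rotational velocity: toward the shorter-stride side
    mean_left = np.mean([amp[l] for l in ("L1", "L2", "L3")], axis=0)
    mean_right = np.mean([amp[l] for l in ("R1", "R2", "R3")], axis=0)
    asym = (mean_left - mean_right) / cfg.base_stride_length
    rot_clean = cfg.rot_gain * asym
    sigma_n = max(1, cfg.rot_smooth_sigma * cfg.rate_velocity)
    rot_clean = gaussian_smooth(rot_clean, 5.0 * sigma_n)  # window = 5 sigma
    rotational = rot_clean + rng_vel.normal(0.0, cfg.noise_sd_velocity, len(t_vel))

    forward_clean = np.where(walking, cfg.forward_base, 0.0)
    for b in cfg.turn_schedule:
        D = envelope_support(b)
        inside = (t_vel >= b.onset) & (t_vel <= b.onset + D)
        env = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t_vel[inside] - b.onset) / D))
        # scale so the realized change from the 10 deg/s bout boundary
        # (where the envelope is already 10/magnitude of full) to the peak
        # equals the commanded forward_delta
        scale = 1.0 / (1.0 - 10.0 / b.magnitude)
        forward_clean[inside] += b.forward_delta * scale * env
    forward = forward_clean + rng_vel.normal(0.0, cfg.noise_sd_velocity, len(t_vel))
    lateral = rng_vel.normal(0.0, cfg.noise_sd_velocity, len(t_vel))

    velocities = VelocityTraces(
        rate=cfg.rate_velocity,
        rotational=rotational,
        forward=forward,
        lateral=lateral,
        rotational_heavy=gaussian_smooth(rotational, 0.1 * cfg.rate_velocity),
        walking_mask=walking,
        meta={"source": "synthetic"},
    )

    # leg trajectories and tracked keypoints (tethered-style placement)
    keypoints = {}
    gt_steps = {}
    bl = cfg.body_length
    for leg in LEGS:
        ap, steps = _leg_trajectory(cfg, leg, t_legs, t_vel, amp[leg])
        gt_steps[leg] = steps
        ml = _ML_CENTER[leg[1]] * (1.0 if leg.startswith("R") else -1.0)
        xy = np.stack([ap * bl, np.full_like(ap, ml * bl)], axis=1)
        if cfg.noise_sd_position > 0:
            xy += rng_pos.normal(0.0, cfg.noise_sd_position * bl, xy.shape)
        keypoints[leg] = xy
    n = len(t_legs)
    fixed = {
        "head": (0.5, 0.0),
        "midpoint_front": (0.25, 0.0),
        "midpoint_mid": (0.0, 0.0),
        "midpoint_hind": (-0.25, 0.0),
        "abdomen": (-0.5, 0.0),
    }
    for name, (x, y) in fixed.items():
        keypoints[name] = np.tile(np.array([x * bl, y * bl]), (n, 1))
    tracked = TrackedSession(
        time=t_legs, keypoints=keypoints, coordinate_space="world_mm", mode="tethered"
    )

    # spike rate leads rotational velocity by neural_lag
    smooth_n = max(1, cfg.neural_kernel_sigma * cfg.rate_velocity)
    rot_for_rate = gaussian_smooth(rot_clean, 5.0 * smooth_n)
    future = np.interp(t_vel + cfg.neural_lag, t_vel, rot_for_rate)
    rate_vals = np.where(
        walking, cfg.neural_baseline + cfg.neural_gain * future, cfg.neural_rest_rate
    )
    rate_true = RateTrace(times=t_vel, rate=np.clip(rate_vals, 0.0, None))
    spikes = simulate_spike_train(rate_true, rng=rng_spk)

    # calcium: indicator kernel -> bleach envelope -> noise
    dt_vel = 1.0 / cfg.rate_velocity
    k_t = np.arange(0.0, 5.0 * cfg.calcium_tau_decay, dt_vel)
    kern = np.exp(-k_t / cfg.calcium_tau_decay) - np.exp(-k_t / cfg.calcium_tau_rise)
    if kern.max() > 0:
        kern = kern / kern.max()
    drive = np.convolve(rate_true.rate, kern)[: len(t_vel)] * dt_vel
    t_ca = np.arange(0.0, total, 1.0 / cfg.rate_calcium)
    drive_ca = np.interp(t_ca, t_vel, drive)
    a1, a2 = cfg.bleach_amps
    tb1, tb2 = cfg.bleach_taus
    bleach = a1 * np.exp(-t_ca / tb1) + a2 * np.exp(-t_ca / tb2)
    f0 = cfg.baseline_fluorescence
    green = f0 * bleach * (1.0 + cfg.calcium_gain * drive_ca)
    red = f0 * bleach
    if cfg.noise_sd_fluorescence > 0:
        green = green + rng_ca.normal(0.0, cfg.noise_sd_fluorescence, len(t_ca))
        red = red + rng_ca.normal(0.0, cfg.noise_sd_fluorescence, len(t_ca))
    cal_g = FluorescenceTrace(times=t_ca, F=green, channel="green")
    cal_r = FluorescenceTrace(times=t_ca, F=red, channel="red")

    realized_bouts = []
    for b in cfg.turn_schedule:
        D = envelope_support(b)
        inside = (t_vel >= b.onset) & (t_vel <= b.onset + D)
        sgn = 1.0 if b.direction == "right" else -1.0
        seg = sgn * rot_clean[inside]
        imax = int(np.argmax(seg))
        realized_bouts.append(
            {
                "onset": b.onset,
                "direction": b.direction,
                "magnitude": b.magnitude,
                "forward_delta": b.forward_delta,
                "peak_time": float(t_vel[inside][imax]),
                "peak_rot_velocity": float(sgn * seg[imax]),
                "target_duration": b.duration,
            }
        )

    ground_truth = {
        "config": cfg,
        "steps": gt_steps,                   # leg -> [(t_pep0, t_aep, t_pep1, stride), ...]
        "bouts": realized_bouts,
        "asymmetry": asym,
        "rot_clean": rot_clean,
        "forward_clean": forward_clean,
        "rate_clean": rate_true.rate.copy(),
        "drive_ca": drive_ca,
        "bleach": bleach,
        "neural_lag": cfg.neural_lag,
    }
    return SyntheticSession(
        config=cfg,
        tracked=tracked,
        velocities_true=velocities,
        rate_true=rate_true,
        spikes=spikes,
        calcium_green=cal_g,
        calcium_red=cal_r,
        ground_truth=ground_truth,
    )


def simulate_spike_train(
    rate: RateTrace, seed: int = None, dead_time: float = 0.002, rng: np.random.Generator = None
) -> SpikeTrain:
    """Inhomogeneous point process with intensity ``rate`` and a dead time.

    Thinning (Lewis-Shedler): homogeneous candidates at the trace maximum are
    accepted with probability ``rate(t)/rate_max``, then any candidate closer
    than ``dead_time`` (2 ms) to the previous accepted spike is dropped, so
    downstream refractory exclusion is a no-op on clean data.
    """
    if np.any(rate.rate < 0):
        raise ValueError("rate must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    lam_max = float(np.max(rate.rate))
    t0, t1 = rate.times[0], rate.times[-1]
    if lam_max <= 0:
        return SpikeTrain(spike_times=np.array([]))
    times = []
    t = t0
    last = -np.inf
    while True:
        t += rng.exponential(1.0 / lam_max)
        if t > t1:
            break
        lam = np.interp(t, rate.times, rate.rate)
        if rng.uniform() < lam / lam_max and t - last >= dead_time:
            times.append(t)
            last = t
    return SpikeTrain(spike_times=np.asarray(times))


def phase_locked_rate(
    phase_deg: np.ndarray,
    times: np.ndarray,
    baseline: float,
    depth: float,
    preferred_deg: float = 90.0,
    offset: float = 0.1,
) -> RateTrace:
    """Firing-rate trace sinusoidally locked to a (future-read) stride phase.

    ``rate(t) = baseline + depth * cos(phase(t - offset) - preferred)``, so a
    spike-phase profile that reads the phase ``offset`` seconds before each
    spike recovers the preferred phase and depth. Phase samples that are NaN
    fall back to the baseline rate.
    """
    t = np.asarray(times, dtype=float)
    ph = np.asarray(phase_deg, dtype=float)
    dt = float(np.median(np.diff(t)))
    shift = int(round(offset / dt))
    ph_shifted = np.full_like(ph, np.nan)
    if shift >= 0:
        ph_shifted[shift:] = ph[: len(ph) - shift] if shift > 0 else ph
    mod = np.where(
        np.isfinite(ph_shifted),
        depth * np.cos(np.radians(ph_shifted - preferred_deg)),
        0.0,
    )
    vals = np.clip(baseline + mod, 0.0, None)
    return RateTrace(times=t, rate=vals)
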