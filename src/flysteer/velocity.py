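"""Body-velocity traces from fictive (spherical-treadmill) or free tracking.

Produces smoothed rotational / forward / lateral velocity and acceleration
traces and a walking mask. Rotational velocity is in deg/s (positive =
rightward), translational velocities in mm/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from ._smoothing import gaussian_smooth

__all__ = [
    "VelocityTraces",
    "process_fictive",
    "process_free",
    "compute_acceleration",
    "detect_walking_bouts",
]


@dataclass
class VelocityTraces:
    """Rotational/forward/lateral velocity (and optional extras) at ``rate`` Hz."""

    rate: float
    rotational: np.ndarray      # deg/s
    forward: np.ndarray         # mm/s
    lateral: np.ndarray         # mm/s
    rotational_heavy: np.ndarray = None
    forward_accel: np.ndarray = None
    rotational_accel: np.ndarray = None
    lateral_accel: np.ndarray = None
    walking_mask: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.rotational)
        for name in ("forward", "lateral"):
            if len(getattr(self, name)) != n:
                raise ValueError("all velocity traces must share one length")

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.rotational)) / self.rate

    @property
    def total_speed(self) -> np.ndarray:
        """Euclidean speed across the three axes (rotational taken as-is)."""
        return np.sqrt(self.rotational**2 + self.forward**2 + self.lateral**2)


def _derivative(x: np.ndarray, rate: float) -> np.ndarray:
    return np.gradient(x) * rate


def process_fictive(
    raw_positions: np.ndarray,
    acquisition_rate: float,
    out_rate: float = 1000.0,
    lowpass_hz: float = 40.0,
    position_window_s: float = 0.200,
    velocity_window_s: float = 0.100,
    with_acceleration: bool = True,
) -> VelocityTraces:
    """Velocities from raw 3-axis sphere-position signals (yaw, pitch, roll).

    Processing order: zero-phase 4th-order Butterworth low-pass at
    ``lowpass_hz``; linear resampling to ``out_rate``; 200-ms Gaussian smooth
    of position; derivative; sign conventions (rotational = -yaw',
    forward = -pitch', lateral = -roll'); 100-ms Gaussian smooth of velocity.

    ``raw_positions`` is ``(n, 3)`` in output units (deg for yaw, mm for
    pitch/roll, i.e. any sphere-radius scaling is already applied).
    """
    pos = np.atleast_2d(np.asarray(raw_positions, dtype=float))
    if pos.shape[1] != 3:
        pos = pos.T
    if pos.shape[1] != 3:
        raise ValueError("raw_positions must have three axes (yaw, pitch, roll)")
    if not np.all(np.isfinite(pos)):
        raise ValueError("raw_positions contain non-finite samples")
    if acquisition_rate < 2 * lowpass_hz:
        warnings.warn(
            f"acquisition rate {acquisition_rate} Hz is below 2x the {lowpass_hz} Hz "
            "low-pass cutoff; filtering skipped near Nyquist",
            stacklevel=2,
        )
    else:
        sos = signal.butter(4, lowpass_hz, fs=acquisition_rate, output="sos")
        pos = np.stack([signal.sosfiltfilt(sos, pos[:, j]) for j in range(3)], axis=1)

    t_in = np.arange(pos.shape[0]) / acquisition_rate
    t_out = np.arange(0.0, t_in[-1] + 0.5 / out_rate, 1.0 / out_rate)
    pos = np.stack([np.interp(t_out, t_in, pos[:, j]) for j in range(3)], axis=1)

    w_pos = position_window_s * out_rate
    pos = np.stack([gaussian_smooth(pos[:, j], w_pos) for j in range(3)], axis=1)

    vel = -np.stack([_derivative(pos[:, j], out_rate) for j in range(3)], axis=1)
    w_vel = velocity_window_s * out_rate
    rot, fwd, lat = (gaussian_smooth(vel[:, j], w_vel) for j in range(3))

    traces = VelocityTraces(
        rate=out_rate,
        rotational=rot,
        forward=fwd,
        lateral=lat,
        meta={
            "source": "fictive",
            "lowpass_hz": lowpass_hz,
            "position_window_s": position_window_s,
            "velocity_window_s": velocity_window_s,
        },
    )
    if with_acceleration:
        traces.rotational_accel = compute_acceleration(rot, out_rate)
        traces.forward_accel = compute_acceleration(fwd, out_rate)
        traces.lateral_accel = compute_acceleration(lat, out_rate)
    return traces


def process_free(
    body_centroid: np.ndarray,
    heading_raw_deg: np.ndarray,
    frame_rate: float,
    leg_heading_reference_deg: np.ndarray = None,
    position_window: int = 10,
    velocity_window: int = 15,
    heavy_window: int = 50,
    with_acceleration: bool = False,
) -> VelocityTraces:
    """Velocities from freely-walking body tracking.

    The raw body-axis orientation (from an ellipse fit) is ambiguous by 180
    degrees; wherever it disagrees with the leg-tracking heading reference by
    more than 90 degrees it is flipped before unwrapping. Position and
    heading get a 10-frame Gaussian smooth; rotational velocity is the
    heading derivative, forward/lateral are the displacement components
    along/orthogonal to the heading; velocities get a 15-frame smooth, and
    the heavily smoothed rotational variant (for turning-bout detection) a
    50-frame smooth instead.
    """
    xy = np.asarray(body_centroid, dtype=float)
    h = np.asarray(heading_raw_deg, dtype=float).copy()
    flips_unresolved = leg_heading_reference_deg is None
    if not flips_unresolved:
        ref = np.asarray(leg_heading_reference_deg, dtype=float)
        need_flip = np.abs(((h - ref + 180.0) % 360.0) - 180.0) > 90.0
        h = np.where(need_flip, h + 180.0, h)
    h = np.degrees(np.unwrap(np.radians(h)))

    x = gaussian_smooth(xy[:, 0], position_window)
    y = gaussian_smooth(xy[:, 1], position_window)
    h = gaussian_smooth(h, position_window)

    rot_raw = _derivative(h, frame_rate)
    vx = _derivative(x, frame_rate)
    vy = _derivative(y, frame_rate)
    hr = np.radians(h)
    fwd_raw = vx * np.cos(hr) + vy * np.sin(hr)
    lat_raw = vx * np.sin(hr) - vy * np.cos(hr)   # positive to the fly's right

    rot = gaussian_smooth(rot_raw, velocity_window)
    fwd = gaussian_smooth(fwd_raw, velocity_window)
    lat = gaussian_smooth(lat_raw, velocity_window)
    heavy = gaussian_smooth(rot_raw, heavy_window)

    traces = VelocityTraces(
        rate=frame_rate,
        rotational=rot,
        forward=fwd,
        lateral=lat,
        rotational_heavy=heavy,
        meta={
            "source": "free",
            "position_window": position_window,
            "velocity_window": velocity_window,
            "heavy_window": heavy_window,
            "flips_unresolved": flips_unresolved,
        },
    )
    if with_acceleration:
        traces.rotational_accel = compute_acceleration(rot, frame_rate)
        traces.forward_accel = compute_acceleration(fwd, frame_rate)
        traces.lateral_accel = compute_acceleration(lat, frame_rate)
    return traces


def compute_acceleration(velocity: np.ndarray, rate: float, window_s: float = 0.250) -> np.ndarray:
    """smooth(250 ms) -> derivative -> smooth(250 ms)."""
    w = window_s * rate
    return gaussian_smooth(_derivative(gaussian_smooth(velocity, w), rate), w)


def _runs(mask: np.ndarray):
    """Run-length encode a boolean mask into (value, length) pairs."""
    out = []
    start = 0
    for i in range(1, len(mask) + 1):
        if i == len(mask) or mask[i] != mask[start]:
            out.append([bool(mask[start]), i - start])
            start = i
    return out


def _merge_adjacent(runs):
    merged = [runs[0]]
    for val, length in runs[1:]:
        if merged[-1][0] == val:
            merged[-1][1] += length
        else:
            merged.append([val, length])
    return merged


def detect_walking_bouts(
    total_speed: np.ndarray,
    rate: float,
    threshold: float,
    middle_leg_speed: np.ndarray = None,
    middle_leg_threshold: float = None,
    min_bout_s: float = 0.200,
) -> np.ndarray:
    """Boolean walking mask with a minimum bout duration.

    Samples below ``threshold`` (and, if given, below ``middle_leg_threshold``
    on the middle-leg speed as well) are preliminarily not-walking. Bouts
    shorter than ``min_bout_s`` are then flipped into their prior bout,
    scanning left to right until every bout meets the minimum; a too-short
    first bout merges into its successor.
    """
    below = np.asarray(total_speed, dtype=float) < threshold
    if middle_leg_speed is not None:
        if middle_leg_threshold is None:
            raise ValueError("middle_leg_threshold required with middle_leg_speed")
        below &= np.asarray(middle_leg_speed, dtype=float) < middle_leg_threshold
    mask = ~below
    min_samples = int(np.ceil(min_bout_s * rate))
    runs = _runs(mask)
    # flip short bouts into their prior bout, scanning left to right; the
    # first bout has no prior and merges into its successor only as a last
    # resort (when it is the only short bout left)
    while len(runs) > 1:
        short = [i for i, (_, length) in enumerate(runs) if length < min_samples]
        if not short:
            break
        i = short[0] if short != [0] else 0
        if i == 0 and len(short) > 1:
            i = short[1]
        runs[i][0] = runs[1][0] if i == 0 else runs[i - 1][0]
        runs = _merge_adjacent(runs)
    out = np.empty(len(mask), dtype=bool)
    pos = 0
    for val, length in runs:
        out[pos : pos + length] = val
        pos += length
    return out
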