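"""Leg kinematics: body-axis fitting, step segmentation, stride parameters.

Converts tracked keypoints (six tarsal tips plus body landmarks) into
body-frame leg trajectories, segments each leg's anterior-posterior (AP)
oscillation into steps (posterior extremum -> anterior extremum -> posterior
extremum), and computes per-step and continuous stride parameters plus a
0-360 degree stride-cycle phase.

Conventions
-----------
* AP coordinates are in units of body length, positive toward the head;
  ML (medial-lateral) coordinates are positive toward the fly's right.
* Step direction is the angle of the AEP->PEP (power stroke) vector measured
  from the straight-backward axis, signed positive when the PEP is displaced
  laterally away from the midline on that leg's side. A straight-backward
  power stroke is 0 degrees; the convention is mirror-symmetric, so swapping
  left and right legs leaves direction values unchanged.
* Frame indices are 0-based; step intervals are half-open [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from scipy.interpolate import PchipInterpolator

LEGS = ("L1", "L2", "L3", "R1", "R2", "R3")

_FREE_AXIS_LANDMARKS = ("head", "postpronotal_left", "postpronotal_right", "scutellum", "abdomen")
_TETHERED_AXIS_LANDMARKS = ("head", "midpoint_front", "midpoint_mid", "midpoint_hind", "abdomen")


@dataclass
class TrackedSession:
    """Per-frame 2-D keypoint positions with timestamps.

    keypoints maps a name (leg tips ``L1``..``R3``, plus the mode's body
    landmarks) to an ``(n_frames, 2)`` array.
    """

    time: np.ndarray
    keypoints: dict
    coordinate_space: str = "world_mm"
    mode: str = "free"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or len(self.time) < 2:
            raise ValueError("time must be a 1-D array with >= 2 frames")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        self.keypoints = {k: np.asarray(v, dtype=float) for k, v in self.keypoints.items()}
        n = len(self.time)
        for name, arr in self.keypoints.items():
            if arr.shape != (n, 2):
                raise ValueError(f"keypoint {name!r} must have shape ({n}, 2)")
        if self.mode not in ("free", "tethered"):
            raise ValueError("mode must be 'free' or 'tethered'")
        required = _FREE_AXIS_LANDMARKS if self.mode == "free" else _TETHERED_AXIS_LANDMARKS
        missing = [k for k in required if k not in self.keypoints]
        if missing:
            raise ValueError(f"session ({self.mode} mode) missing landmarks: {missing}")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def legs_present(self):
        return [leg for leg in LEGS if leg in self.keypoints]


@dataclass
class BodyFrame:
    """Per-frame body axis: unit AP axis, midpoint, body length and heading."""

    ap_axis: np.ndarray          # (n, 2) unit vectors, pointing toward the head
    midpoint: np.ndarray         # (n, 2)
    body_length: np.ndarray      # (n,) head-abdomen distance along the axis
    heading_deg: np.ndarray      # (n,) facing direction (angle of ap_axis)

    @property
    def ml_axis(self) -> np.ndarray:
        """Unit vectors pointing to the fly's right."""
        return np.stack([self.ap_axis[:, 1], -self.ap_axis[:, 0]], axis=1)


@dataclass
class Step:
    """One complete step cycle (posterior -> anterior -> posterior)."""

    leg: str
    start: int
    mid: int
    end: int
    start_time: float
    mid_time: float
    end_time: float
    aep: tuple                   # (AP, ML) at the anterior extremum, body lengths
    pep: tuple                   # (AP, ML) at the closing posterior extremum
    stride_length: float         # AP(AEP) - AP(PEP), body lengths
    step_direction_deg: float    # side-signed AEP->PEP angle, (-180, 180]
    swing_half: str              # 'first' or 'second'
    swing_tied: bool = False
    return_stroke_pos: tuple = None
    power_stroke_pos: tuple = None

    def __post_init__(self):
        if not (self.start < self.mid < self.end):
            raise ValueError("step frames must satisfy start < mid < end")


@dataclass
class StepContinuum:
    """Continuous (per-frame) stride-parameter estimates for one leg."""

    leg: str
    aep_ap: np.ndarray
    aep_ml: np.ndarray
    pep_ap: np.ndarray
    pep_ml: np.ndarray
    stride_length: np.ndarray
    step_direction_deg: np.ndarray
    phase_deg: np.ndarray = None
    valid: np.ndarray = None
    is_valid: bool = True


def fit_body_axis(session: TrackedSession) -> BodyFrame:
    """Fit the per-frame anterior-posterior body axis by total least squares.

    Free mode fits the line through the head, the midpoint between the
    postpronotal lobes, the scutellum tip and the abdomen tip; tethered mode
    uses the head, the three between-leg midpoints and the abdomen. The head
    and abdomen are projected onto the line; their separation defines the
    body length and the scutellum (free) or middle-leg midpoint (tethered)
    projects to the body midpoint.
    """
    kp = session.keypoints
    if session.mode == "free":
        ppl = 0.5 * (kp["postpronotal_left"] + kp["postpronotal_right"])
        pts = np.stack([kp["head"], ppl, kp["scutellum"], kp["abdomen"]], axis=1)
        mid_marker = kp["scutellum"]
    else:
        pts = np.stack(
            [kp["head"], kp["midpoint_front"], kp["midpoint_mid"], kp["midpoint_hind"], kp["abdomen"]],
            axis=1,
        )
        mid_marker = kp["midpoint_mid"]

    center = pts.mean(axis=1)                      # (n, 2)
    c = pts - center[:, None, :]
    # 2x2 scatter per frame -> major axis in closed form
    sxx = np.einsum("nk,nk->n", c[:, :, 0], c[:, :, 0])
    syy = np.einsum("nk,nk->n", c[:, :, 1], c[:, :, 1])
    sxy = np.einsum("nk,nk->n", c[:, :, 0], c[:, :, 1])
    if np.any((sxx + syy) <= 0):
        raise ValueError("degenerate landmark configuration (all points coincident)")
    theta = 0.5 * np.arctan2(2 * sxy, sxx - syy)
    axis = np.stack([np.cos(theta), np.sin(theta)], axis=1)

    # orient toward the head
    head_vec = kp["head"] - kp["abdomen"]
    flip = np.einsum("nk,nk->n", axis, head_vec) < 0
    axis[flip] *= -1.0

    proj = lambda p: center + np.einsum("nk,nk->n", p - center, axis)[:, None] * axis
    head_p, abd_p, mid_p = proj(kp["head"]), proj(kp["abdomen"]), proj(mid_marker)
    body_length = np.linalg.norm(head_p - abd_p, axis=1)
    if np.any(body_length <= 0):
        raise ValueError("degenerate landmark configuration (zero body length)")
    heading = np.degrees(np.arctan2(axis[:, 1], axis[:, 0]))
    return BodyFrame(ap_axis=axis, midpoint=mid_p, body_length=body_length, heading_deg=heading)


def to_body_frame(session: TrackedSession, frame: BodyFrame, keys=None) -> dict:
    """Project keypoints into body coordinates (units of body length).

    Returns ``{name: (n, 2) array}`` with columns (AP, ML); AP positive
    toward the head, ML positive to the fly's right.
    """
    keys = session.legs_present() if keys is None else keys
    ml = frame.ml_axis
    out = {}
    for name in keys:
        rel = session.keypoints[name] - frame.midpoint
        ap_c = np.einsum("nk,nk->n", rel, frame.ap_axis) / frame.body_length
        ml_c = np.einsum("nk,nk->n", rel, ml) / frame.body_length
        out[name] = np.stack([ap_c, ml_c], axis=1)
    return out


def remove_position_outliers(
    trace: np.ndarray, median_window: int = 5, range_window: int = 500
) -> np.ndarray:
    """Replace tracking glitches with the local median-filtered value.

    A sample is an outlier when it deviates from the ``median_window``-frame
    running median by more than 50% of the range of median-filtered values in
    a centered ``range_window``-frame window. Windows truncate at the trace
    edges. A zero local range makes any nonzero deviation an outlier, so
    constant traces pass through except for true spikes.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim == 2:
        return np.stack(
            [remove_position_outliers(x[:, j], median_window, range_window) for j in range(x.shape[1])],
            axis=1,
        )
    if len(x) < median_window:
        return x.copy()
    med = ndimage.median_filter(x, size=median_window, mode="nearest")
    hi = ndimage.maximum_filter1d(med, size=range_window, mode="nearest")
    lo = ndimage.minimum_filter1d(med, size=range_window, mode="nearest")
    rng = hi - lo
    outlier = np.abs(x - med) > 0.5 * rng
    return np.where(outlier, med, x)


def _alternate(indices, kinds, values):
    """Enforce min/max alternation, keeping the more extreme of same-kind runs."""
    out_i, out_k = [], []
    for i, k in zip(indices, kinds):
        if out_k and out_k[-1] == k:
            better = values[i] > values[out_i[-1]] if k == "max" else values[i] < values[out_i[-1]]
            if better:
                out_i[-1] = i
        else:
            out_i.append(i)
            out_k.append(k)
    return out_i, out_k


def find_ap_extrema(
    ap_position: np.ndarray,
    time: np.ndarray = None,
    min_excursion: float = 0.02,
    min_half_duration: float = 0.010,
):
    """Alternating minima/maxima of an AP position series.

    Peaks and troughs are detected with a prominence threshold
    (``min_excursion``, body lengths) to reject jitter, forced to alternate,
    and half steps shorter than ``min_half_duration`` seconds are pruned by
    removing the offending extremum pair. Returns ``(indices, kinds)`` with
    kinds in {'min', 'max'}.
    """
    x = np.asarray(ap_position, dtype=float)
    if len(x) < 3:
        return [], []
    maxima, _ = signal.find_peaks(x, prominence=min_excursion)
    minima, _ = signal.find_peaks(-x, prominence=min_excursion)
    idx = np.concatenate([maxima, minima])
    kinds = ["max"] * len(maxima) + ["min"] * len(minima)
    order = np.argsort(idx, kind="stable")
    idx = idx[order]
    kinds = [kinds[i] for i in order]
    out_i, out_k = _alternate(idx, kinds, x)

    if time is None:
        time = np.arange(len(x), dtype=float)
    # prune half steps shorter than the minimum duration
    changed = True
    while changed and len(out_i) >= 2:
        changed = False
        for j in range(len(out_i) - 1):
            if time[out_i[j + 1]] - time[out_i[j]] < min_half_duration:
                del out_i[j : j + 2], out_k[j : j + 2]
                out_i, out_k = _alternate(out_i, out_k, x)
                changed = True
                break
    return out_i, out_k


def segment_steps(
    ap_position: np.ndarray,
    time: np.ndarray = None,
    min_excursion: float = 0.02,
    min_half_duration: float = 0.010,
):
    """Segment one leg's AP series into (min, max, min) extrema triplets.

    Each triplet is one complete step cycle from posterior to anterior to
    posterior extremum; partial cycles at the trace edges are discarded.
    Returns a list of ``(i_start, i_mid, i_end)`` frame-index tuples.
    """
    idx, kinds = find_ap_extrema(ap_position, time, min_excursion, min_half_duration)
    if len(idx) < 3:
        return []
    try:
        first_min = kinds.index("min")
    except ValueError:
        return []
    triplets = []
    for j in range(first_min, len(idx) - 2, 2):
        if kinds[j] == "min" and kinds[j + 1] == "max" and kinds[j + 2] == "min":
            triplets.append((int(idx[j]), int(idx[j + 1]), int(idx[j + 2])))
    return triplets


def _side_sign(leg: str) -> float:
    return 1.0 if leg.startswith("R") else -1.0


def step_direction_deg(leg: str, aep, pep) -> float:
    """Side-signed angle of the AEP->PEP vector (0 deg = straight backward)."""
    v_ap = pep[0] - aep[0]
    v_ml = pep[1] - aep[1]
    ang = np.degrees(np.arctan2(_side_sign(leg) * v_ml, -v_ap))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def compute_step_parameters(
    triplet,
    ap: np.ndarray,
    ml: np.ndarray,
    time: np.ndarray,
    leg: str,
    mode: str = "free",
    world_xy: np.ndarray = None,
) -> Step:
    """Per-step parameters from one (min, max, min) extrema triplet.

    Swing/stance assignment follows the session mode: in free mode the half
    step with the larger mean world-frame leg-tip speed is swing (the leg is
    moving relative to the ground); in tethered mode the shorter half step is
    swing (swing is always briefer than stance). Ties label the first half
    swing and set ``swing_tied``.
    """
    i0, i1, i2 = triplet
    t0, t1, t2 = time[i0], time[i1], time[i2]
    if t1 - t0 <= 0 or t2 - t1 <= 0:
        raise ValueError("zero-duration half step")
    aep = (float(ap[i1]), float(ml[i1]))
    pep = (float(ap[i2]), float(ml[i2]))
    tied = False
    if mode == "tethered":
        d_first, d_second = t1 - t0, t2 - t1
        tied = np.isclose(d_first, d_second)
        swing_half = "first" if d_first <= d_second else "second"
    else:
        if world_xy is None:
            raise ValueError("free-mode swing/stance needs world-frame leg positions")
        seg = np.linalg.norm(np.diff(world_xy, axis=0), axis=1) / np.diff(time)
        v_first = float(np.mean(seg[i0:i1]))
        v_second = float(np.mean(seg[i1:i2]))
        tied = np.isclose(v_first, v_second)
        swing_half = "first" if v_first >= v_second else "second"
    return Step(
        leg=leg,
        start=int(i0),
        mid=int(i1),
        end=int(i2),
        start_time=float(t0),
        mid_time=float(t1),
        end_time=float(t2),
        aep=aep,
        pep=pep,
        stride_length=float(ap[i1] - ap[i2]),
        step_direction_deg=step_direction_deg(leg, aep, pep),
        swing_half=swing_half,
        swing_tied=bool(tied),
        return_stroke_pos=aep,
        power_stroke_pos=pep,
    )


def compute_continuous_estimates(
    ap: np.ndarray,
    ml: np.ndarray,
    time: np.ndarray,
    extrema_idx,
    extrema_kinds,
    leg: str,
) -> StepContinuum:
    """Continuous AEP/PEP/stride-length/step-direction estimates for one leg.

    Monotone (PCHIP) cubic interpolation through the AP maxima gives the
    continuous AEP, and through the minima the continuous PEP; their AP
    difference is the continuous stride length. The estimate is flagged valid
    only between the first and last knots common to both sides.
    """
    idx = np.asarray(extrema_idx, dtype=int)
    kinds = np.asarray(extrema_kinds)
    max_i = idx[kinds == "max"]
    min_i = idx[kinds == "min"]
    n = len(ap)
    nanarr = lambda: np.full(n, np.nan)
    if len(max_i) < 2 or len(min_i) < 2:
        return StepContinuum(
            leg, nanarr(), nanarr(), nanarr(), nanarr(), nanarr(), nanarr(),
            valid=np.zeros(n, bool), is_valid=False,
        )
    aep_ap = PchipInterpolator(time[max_i], ap[max_i])(time)
    aep_ml = PchipInterpolator(time[max_i], ml[max_i])(time)
    pep_ap = PchipInterpolator(time[min_i], ap[min_i])(time)
    pep_ml = PchipInterpolator(time[min_i], ml[min_i])(time)
    stride = aep_ap - pep_ap
    sgn = _side_sign(leg)
    direction = np.degrees(np.arctan2(sgn * (pep_ml - aep_ml), -(pep_ap - aep_ap)))
    lo = max(time[max_i[0]], time[min_i[0]])
    hi = min(time[max_i[-1]], time[min_i[-1]])
    valid = (time >= lo) & (time <= hi)
    return StepContinuum(leg, aep_ap, aep_ml, pep_ap, pep_ml, stride, direction, valid=valid)


def compute_leg_phase(ap: np.ndarray, steps) -> np.ndarray:
    """Per-frame stride-cycle phase in degrees, NaN outside segmented steps.

    Phase is 0 at swing onset, 180 at the swing/stance transition and 360 at
    stance end, linearly interpolated within each half step using the AP
    position (clamped to the half step's anchor range), and stored mod 360.
    """
    phase = np.full(len(ap), np.nan)
    for st in steps:
        halves = [(st.start, st.mid), (st.mid, st.end)]
        swing_first = st.swing_half == "first"
        for h, (a, b) in enumerate(halves):
            x0, x1 = ap[a], ap[b]
            lo, hi = (0.0, 180.0) if (h == 0) == swing_first else (180.0, 360.0)
            sl = slice(a, b)
            if x1 == x0:
                frac = np.zeros(b - a)
            else:
                frac = (ap[sl] - x0) / (x1 - x0)
            frac = np.clip(frac, 0.0, 1.0)
            phase[sl] = (lo + frac * (hi - lo)) % 360.0
    return phase


def leg_analysis(
    session: TrackedSession,
    min_excursion: float = 0.02,
    min_half_duration: float = 0.010,
    clean_outliers: bool = True,
):
    """Full per-leg kinematic analysis of a tracked session.

    Fits the body axis, projects the leg tips, segments steps and computes
    step parameters, continuous estimates and phase for every leg present.
    Returns ``(frame, steps, continuum)`` where ``steps`` and ``continuum``
    map leg names to lists of :class:`Step` / :class:`StepContinuum`.
    """
    frame = fit_body_axis(session)
    body = to_body_frame(session, frame)
    steps, continuum = {}, {}
    for leg in session.legs_present():
        pos = body[leg]
        if clean_outliers:
            pos = remove_position_outliers(pos)
        ap, ml = pos[:, 0], pos[:, 1]
        idx, kinds = find_ap_extrema(ap, session.time, min_excursion, min_half_duration)
        triplets = segment_steps(ap, session.time, min_excursion, min_half_duration)
        leg_steps = [
            compute_step_parameters(
                tr, ap, ml, session.time, leg, mode=session.mode,
                world_xy=session.keypoints[leg],
            )
            for tr in triplets
        ]
        cont = compute_continuous_estimates(ap, ml, session.time, idx, kinds, leg)
        cont.phase_deg = compute_leg_phase(ap, leg_steps)
        steps[leg] = leg_steps
        continuum[leg] = cont
    return frame, steps, continuum


def step_table(steps: dict) -> pd.DataFrame:
    """Flatten a ``{leg: [Step, ...]}`` mapping into one row per step."""
    rows = []
    for leg, items in steps.items():
        for st in items:
            rows.append(
                {
                    "leg": leg,
                    "start": st.start,
                    "mid": st.mid,
                    "end": st.end,
                    "start_time": st.start_time,
                    "mid_time": st.mid_time,
                    "end_time": st.end_time,
                    "aep_ap": st.aep[0],
                    "aep_ml": st.aep[1],
                    "pep_ap": st.pep[0],
                    "pep_ml": st.pep[1],
                    "stride_length": st.stride_length,
                    "step_direction_deg": st.step_direction_deg,
                    "swing_half": st.swing_half,
                }
            )
    return pd.DataFrame(rows)
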