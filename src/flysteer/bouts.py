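"""Turning-bout detection, canonicalization and pivot/swerve taxonomy.

A turning bout is a peak in the heavily smoothed rotational velocity,
bounded by the nearest crossings below 10 deg/s on either side, with a
duration of 0.3-0.7 s. Left turns are canonicalized into right turns so
bouts can be pooled: rotational velocity is sign-inverted and left/right leg
labels are swapped ("outside" = contralateral to the turn, "inside" =
ipsilateral). Bouts where forward velocity drops by more than 1 mm/s from
bout start to the rotational peak are pivots; bouts where it rises by more
than 1 mm/s are swerves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .kinematics import LEGS

__all__ = [
    "TurningBout",
    "BoutStepDeltas",
    "detect_turning_bouts",
    "canonicalize_left_turns",
    "mirror_steps",
    "classify_pivot_swerve",
    "not_turning_reference",
    "step_deltas_at_peak",
    "bout_triggered_stride",
]

BOUNDARY_DEG_S = 10.0
MIN_DURATION_S = 0.3
MAX_DURATION_S = 0.7


@dataclass
class TurningBout:
    peak_time: float
    start_time: float
    end_time: float
    peak_rot_velocity: float        # deg/s; positive once canonicalized
    direction_original: str         # 'left' or 'right'
    forward_at_start: float = np.nan
    forward_at_peak: float = np.nan
    category: str = None            # 'pivot' | 'swerve' | 'neither'
    canonical: bool = False

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    @property
    def forward_delta(self) -> float:
        return self.forward_at_peak - self.forward_at_start


@dataclass
class BoutStepDeltas:
    """Per-leg step-parameter changes at the bout's rotational peak.

    Keys of the per-leg dicts are canonical leg names (after any left-turn
    mirroring): R legs are inside the turn, L legs outside. Values are
    expressed relative to the not-turning reference mean for that leg.
    """

    bout: TurningBout
    d_stride_length: dict = field(default_factory=dict)
    d_step_direction: dict = field(default_factory=dict)
    d_return_stroke: dict = field(default_factory=dict)    # (AP, ML)
    d_power_stroke: dict = field(default_factory=dict)     # (AP, ML)
    missing_legs: list = field(default_factory=list)


def _interp_crossing(t, x, i, j, level):
    """Sub-sample time where x crosses ``level`` between samples i and j."""
    if x[j] == x[i]:
        return t[j]
    frac = (x[i] - level) / (x[i] - x[j])
    return t[i] + frac * (t[j] - t[i])


def detect_turning_bouts(
    rotational_heavy: np.ndarray,
    rate: float,
    forward: np.ndarray = None,
    min_peak: float = 20.0,
    boundary: float = BOUNDARY_DEG_S,
    min_duration: float = MIN_DURATION_S,
    max_duration: float = MAX_DURATION_S,
    min_separation: float = 0.3,
    time0: float = 0.0,
):
    """Detect turning bouts in the heavily smoothed rotational velocity.

    Peaks above ``min_peak`` are found separately in the trace (right turns)
    and its negation (left turns). Each peak is walked outward to the nearest
    sub-sample crossings below ``boundary`` (in the turn's sign) to set the
    bout start/end; only bouts with durations in
    ``[min_duration, max_duration]`` survive, and of two bouts sharing an
    epoch the one with the larger peak is kept. ``forward`` (the lightly
    smoothed forward velocity) fills ``forward_at_start`` / ``forward_at_peak``.
    """
    x = np.asarray(rotational_heavy, dtype=float)
    n = len(x)
    if n / rate < max_duration:
        return []
    t = time0 + np.arange(n) / rate
    dist = max(1, int(round(min_separation * rate)))
    candidates = []
    for sgn, direction in ((1.0, "right"), (-1.0, "left")):
        peaks, _ = signal.find_peaks(sgn * x, height=min_peak, distance=dist)
        for p in peaks:
            s = sgn * x
            i = p
            while i > 0 and s[i - 1] > boundary:
                i -= 1
            if i == 0 and s[0] > boundary:
                continue  # bout start outside the trace
            start = _interp_crossing(t, s, i - 1, i, boundary) if i > 0 else t[0]
            j = p
            while j < n - 1 and s[j + 1] > boundary:
                j += 1
            if j == n - 1 and s[n - 1] > boundary:
                continue
            end = _interp_crossing(t, s, j, j + 1, boundary) if j < n - 1 else t[-1]
            dur = end - start
            if not (min_duration <= dur <= max_duration):
                continue
            candidates.append(
                TurningBout(
                    peak_time=float(t[p]),
                    start_time=float(start),
                    end_time=float(end),
                    peak_rot_velocity=float(x[p]),
                    direction_original=direction,
                )
            )
    # resolve overlaps: keep the larger |peak|
    candidates.sort(key=lambda b: -abs(b.peak_rot_velocity))
    kept = []
    for b in candidates:
        if all(b.end_time <= k.start_time or b.start_time >= k.end_time for k in kept):
            kept.append(b)
    kept.sort(key=lambda b: b.peak_time)
    if forward is not None:
        fwd = np.asarray(forward, dtype=float)
        for b in kept:
            b.forward_at_start = float(np.interp(b.start_time, t, fwd))
            b.forward_at_peak = float(np.interp(b.peak_time, t, fwd))
    return kept


_MIRROR = {leg: ("R" if leg[0] == "L" else "L") + leg[1] for leg in LEGS}


def mirror_steps(steps: pd.DataFrame) -> pd.DataFrame:
    """Swap left/right leg labels and mirror ML coordinates of a step table.

    Step direction values are left unchanged: the side-signed direction
    convention (positive = away from the midline on the leg's own side)
    already folds the mirror symmetry, so only labels and ML signs flip.
    """
    out = steps.copy()
    out["leg"] = out["leg"].map(_MIRROR)
    for col in ("aep_ml", "pep_ml"):
        if col in out.columns:
            out[col] = -out[col]
    return out


def canonicalize_left_turns(bouts, steps: pd.DataFrame = None):
    """Canonicalize bouts (and per-bout step data) so every turn is rightward.

    Left-turn bouts get their rotational velocity sign-inverted and their
    step table mirrored (leg labels swapped); right turns pass through.
    After canonicalization the R legs are the inside of the turn and the L
    legs the outside. Returns ``(bouts, steps_by_bout)``; the second element
    is None when no step table is given. Applying the transform twice
    restores the original data (involution), which
    :func:`tests <mirror_steps>` assert.
    """
    out_bouts = []
    steps_by_bout = None if steps is None else []
    for b in bouts:
        if b.canonical or b.peak_rot_velocity >= 0:
            nb = replace(b, canonical=True)
            sb = steps
        else:
            nb = replace(b, peak_rot_velocity=-b.peak_rot_velocity, canonical=True)
            sb = mirror_steps(steps) if steps is not None else None
        out_bouts.append(nb)
        if steps_by_bout is not None:
            steps_by_bout.append(sb)
    return out_bouts, steps_by_bout


def classify_pivot_swerve(bout: TurningBout, threshold: float = 1.0) -> str:
    """Pivot (forward velocity drops > threshold), swerve (rises), or neither.

    The difference is forward velocity at the rotational peak minus at the
    bout start, read from the lightly smoothed forward trace.
    """
    d = bout.forward_delta
    if np.isnan(d):
        raise ValueError("bout has no forward-velocity samples")
    if d < -threshold:
        cat = "pivot"
    elif d > threshold:
        cat = "swerve"
    else:
        cat = "neither"
    bout.category = cat
    return cat


def not_turning_reference(
    steps: pd.DataFrame,
    rot_time: np.ndarray,
    rot: np.ndarray,
    threshold: float = BOUNDARY_DEG_S,
) -> dict:
    """Per-leg mean step parameters when the fly is not turning.

    A step counts as not-turning when the rotational speed at its mid time is
    below ``threshold`` (default 10 deg/s). Step-direction means are circular.
    """
    speed = np.abs(np.interp(steps["mid_time"], rot_time, rot))
    quiet = steps[speed < threshold]
    ref = {}
    for leg, grp in quiet.groupby("leg"):
        ang = np.radians(grp["step_direction_deg"])
        circ_mean = np.degrees(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()))
        ref[leg] = {
            "stride_length": float(grp["stride_length"].mean()),
            "step_direction_deg": float(circ_mean),
            "aep_ap": float(grp["aep_ap"].mean()),
            "aep_ml": float(grp["aep_ml"].mean()),
            "pep_ap": float(grp["pep_ap"].mean()),
            "pep_ml": float(grp["pep_ml"].mean()),
        }
    return ref


def _circ_diff_deg(a, b):
    return (a - b + 180.0) % 360.0 - 180.0


def step_deltas_at_peak(bout: TurningBout, steps: pd.DataFrame, reference: dict) -> BoutStepDeltas:
    """Step-parameter deltas at the bout's rotational-velocity peak.

    For each leg, the step whose ``[start_time, end_time)`` interval contains
    the peak supplies the values; deltas are taken against the not-turning
    reference for that leg. Legs without a covering step (or reference) are
    flagged missing and the bout is retained.
    """
    out = BoutStepDeltas(bout=bout)
    for leg in LEGS:
        sub = steps[steps["leg"] == leg]
        cover = sub[(sub["start_time"] <= bout.peak_time) & (bout.peak_time < sub["end_time"])]
        if len(cover) == 0 or leg not in reference:
            out.missing_legs.append(leg)
            continue
        st = cover.iloc[0]
        ref = reference[leg]
        out.d_stride_length[leg] = float(st["stride_length"] - ref["stride_length"])
        out.d_step_direction[leg] = float(
            _circ_diff_deg(st["step_direction_deg"], ref["step_direction_deg"])
        )
        out.d_return_stroke[leg] = (
            float(st["aep_ap"] - ref["aep_ap"]),
            float(st["aep_ml"] - ref["aep_ml"]),
        )
        out.d_power_stroke[leg] = (
            float(st["pep_ap"] - ref["pep_ap"]),
            float(st["pep_ml"] - ref["pep_ml"]),
        )
    return out


def select_bouts(
    bouts,
    forward_window=None,
    forward_at="start",
    peak_window=None,
):
    """Apply the optional bout-selection filters (forward and peak windows)."""
    keep = []
    for b in bouts:
        if forward_window is not None:
            v = b.forward_at_start if forward_at == "start" else b.forward_at_peak
            if not (forward_window[0] <= v <= forward_window[1]):
                continue
        if peak_window is not None:
            if not (peak_window[0] <= abs(b.peak_rot_velocity) <= peak_window[1]):
                continue
        keep.append(b)
    return keep


def bout_triggered_stride(
    bouts,
    stride_time: np.ndarray,
    stride_by_leg: dict,
    window_s: float = 0.5,
    out_rate: float = 100.0,
    peak_search_s: float = 0.2,
):
    """Bout-triggered, min-max-normalized stride-length time courses + FWHM.

    Continuous stride-length snippets from ``-window_s`` to ``+window_s``
    around each bout's rotational peak are interpolated to ``out_rate``,
    normalized per bout by (x - min)/(max - min), and averaged per leg across
    bouts; the mean is re-normalized to [0, 1]. The per-bout FWHM is the time
    spent above half of the maximum found within ``+-peak_search_s`` of the
    peak (contiguous region, sub-sample boundaries). Bouts whose snippet
    leaves the trace or has zero range are skipped and counted.
    """
    rel = np.arange(-window_s, window_s + 0.5 / out_rate, 1.0 / out_rate)
    mean_traces, fwhm, n_skipped = {}, {}, {}
    for leg, stride in stride_by_leg.items():
        snippets, widths, skipped = [], [], 0
        for b in bouts:
            tt = b.peak_time + rel
            if tt[0] < stride_time[0] or tt[-1] > stride_time[-1]:
                skipped += 1
                continue
            snip = np.interp(tt, stride_time, stride)
            rng = snip.max() - snip.min()
            if rng <= 0:
                skipped += 1
                continue
            norm = (snip - snip.min()) / rng
            snippets.append(norm)
            widths.append(_fwhm_of_snippet(rel, norm, peak_search_s))
        if snippets:
            mean = np.mean(snippets, axis=0)
            mrng = mean.max() - mean.min()
            mean = (mean - mean.min()) / mrng if mrng > 0 else mean
        else:
            mean = np.full_like(rel, np.nan)
        mean_traces[leg] = mean
        fwhm[leg] = np.asarray(widths)
        n_skipped[leg] = skipped
    return {"lags": rel, "mean": mean_traces, "fwhm": fwhm, "skipped": n_skipped}


def _fwhm_of_snippet(rel, snip, peak_search_s):
    """Time above half of the maximum within +-peak_search_s of the trigger."""
    win = np.abs(rel) <= peak_search_s
    i_local = int(np.argmax(snip[win]))
    imax = np.flatnonzero(win)[i_local]
    half = snip[imax] / 2.0
    lo = imax
    while lo > 0 and snip[lo - 1] > half:
        lo -= 1
    hi = imax
    while hi < len(snip) - 1 and snip[hi + 1] > half:
        hi += 1
    t_lo = rel[lo] if lo == 0 else _interp_crossing(rel, snip, lo - 1, lo, half)
    t_hi = rel[hi] if hi == len(snip) - 1 else _interp_crossing(rel, snip, hi, hi + 1, half)
    return float(t_hi - t_lo)
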