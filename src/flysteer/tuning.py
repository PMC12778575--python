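"""Neural-behavior tuning curves and stride-phase spike locking.

Binned tuning curves pair a behavioral series with the neural series a fixed
offset earlier (100 ms by default, since descending-neuron spikes precede
their behavioral consequences); phase analyses assign spikes to stride-cycle
phase bins read the same offset before each spike and normalize by the time
spent at each phase. All phase arithmetic is circular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TuningCurve",
    "PhaseProfile",
    "binned_tuning",
    "split_by_turning",
    "conditioned_rate",
    "common_stride_phase",
    "spike_phase_profile",
    "phase_modulation_depth",
    "forward_stepping_mask",
]


@dataclass
class TuningCurve:
    bin_centers: np.ndarray
    bin_means: np.ndarray        # NaN where count < min_count
    bin_counts: np.ndarray
    pearson_r: float
    min_count: int
    lag_offset: float
    n_samples: int = 0
    empty: bool = False


@dataclass
class PhaseProfile:
    bin_edges: np.ndarray        # degrees, len n_bins + 1
    rate_modulation: np.ndarray  # spikes/s, difference from the occupancy-weighted mean
    occupancy: np.ndarray        # s per bin
    offset: float                # s; phase read this long before each spike
    n_spikes: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _lag_pairs(x, y, rate, lag_offset, mask):
    """Pair x(t) with y(t - lag_offset) on a common grid (nearest sample)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    shift = int(round(lag_offset * rate))
    if shift > 0:
        xs, ys = x[shift:], y[:-shift]
        m = np.ones(len(x), bool) if mask is None else np.asarray(mask, bool)
        ms = m[shift:]
    elif shift < 0:
        xs, ys = x[:shift], y[-shift:]
        m = np.ones(len(x), bool) if mask is None else np.asarray(mask, bool)
        ms = m[:shift]
    else:
        xs, ys = x, y
        ms = np.ones(len(x), bool) if mask is None else np.asarray(mask, bool)
    good = ms & np.isfinite(xs) & np.isfinite(ys)
    return xs[good], ys[good]


def binned_tuning(
    x: np.ndarray,
    y: np.ndarray,
    rate: float,
    n_bins: int = 50,
    min_count: int = 50,
    lag_offset: float = 0.1,
    mask: np.ndarray = None,
) -> TuningCurve:
    """Tuning curve of ``y`` (shifted ``lag_offset`` earlier) against ``x``.

    Equal-width bins span the observed range of the masked ``x`` samples;
    bins with fewer than ``min_count`` samples are excluded from the means.
    The Pearson r is computed on the same masked, lagged sample pairs.
    """
    xs, ys = _lag_pairs(x, y, rate, lag_offset, mask)
    if len(xs) == 0:
        raise ValueError("no samples after masking")
    lo, hi = xs.min(), xs.max()
    if hi == lo:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(xs, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=ys, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts >= max(min_count, 1), sums / np.maximum(counts, 1), np.nan)
    if np.std(xs) == 0 or np.std(ys) == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(xs, ys)[0, 1])
    return TuningCurve(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        bin_means=means,
        bin_counts=counts,
        pearson_r=r,
        min_count=min_count,
        lag_offset=lag_offset,
        n_samples=len(xs),
    )


def split_by_turning(
    x, y, rate, rot_velocity, threshold: float = 25.0, mask=None, **tuning_kwargs
):
    """Tuning curves for turning (|rot| >= threshold) and not-turning samples."""
    rot_speed = np.abs(np.asarray(rot_velocity, dtype=float))
    base = np.ones(len(rot_speed), bool) if mask is None else np.asarray(mask, bool)
    out = []
    for cond in (rot_speed >= threshold, rot_speed < threshold):
        m = base & cond
        if not m.any():
            out.append(
                TuningCurve(
                    bin_centers=np.array([]), bin_means=np.array([]),
                    bin_counts=np.array([], int), pearson_r=np.nan,
                    min_count=tuning_kwargs.get("min_count", 50),
                    lag_offset=tuning_kwargs.get("lag_offset", 0.1), empty=True,
                )
            )
        else:
            out.append(binned_tuning(x, y, rate, mask=m, **tuning_kwargs))
    turning, not_turning = out
    return turning, not_turning


def conditioned_rate(
    norm_rate: np.ndarray,
    rot_velocity: np.ndarray,
    forward_accel: np.ndarray,
    rate: float,
    rot_window=(50.0, 100.0),
    accel_threshold: float = 10.0,
    pre_window_s: float = 0.1,
    mask: np.ndarray = None,
):
    """Mean normalized rate preceding decelerating vs accelerating turns.

    Time points turning inside ``rot_window`` (signed, i.e. ipsiversive) are
    split by forward acceleration (< -threshold decelerating,
    > +threshold accelerating); for each qualifying point the normalized rate
    is averaged over the preceding ``pre_window_s``. Returns a dict with the
    per-condition means, their difference and the sample counts (NaN means
    and a flag when a condition has no qualifying points).
    """
    r = np.asarray(norm_rate, dtype=float)
    rot = np.asarray(rot_velocity, dtype=float)
    acc = np.asarray(forward_accel, dtype=float)
    base = np.ones(len(r), bool) if mask is None else np.asarray(mask, bool)
    n_pre = max(1, int(round(pre_window_s * rate)))
    csum = np.concatenate([[0.0], np.cumsum(r)])
    idx = np.arange(len(r))
    pre_mean = np.full(len(r), np.nan)
    ok = idx + 1 >= n_pre
    pre_mean[ok] = (csum[idx[ok] + 1] - csum[idx[ok] + 1 - n_pre]) / n_pre

    qualify = base & (rot >= rot_window[0]) & (rot <= rot_window[1]) & np.isfinite(pre_mean)
    out = {}
    for name, cond in (("decelerating", acc < -accel_threshold), ("accelerating", acc > accel_threshold)):
        sel = qualify & cond
        out[f"n_{name}"] = int(sel.sum())
        out[f"mean_{name}"] = float(np.mean(pre_mean[sel])) if sel.any() else np.nan
    out["difference"] = out["mean_decelerating"] - out["mean_accelerating"]
    return out


def _circ_mean_deg(deg, axis=None, weights=None):
    ang = np.radians(np.asarray(deg, dtype=float))
    if weights is None:
        s, c = np.nanmean(np.sin(ang), axis=axis), np.nanmean(np.cos(ang), axis=axis)
    else:
        w = np.asarray(weights, dtype=float)
        s = np.nansum(w * np.sin(ang), axis=axis)
        c = np.nansum(w * np.cos(ang), axis=axis)
    return np.degrees(np.arctan2(s, c)) % 360.0


def common_stride_phase(phases: dict, reference_leg: str):
    """Average stride-cycle phase across legs, aligned to a reference leg.

    Each leg's phase is shifted by the circular mean of its offset to the
    reference leg, then the per-frame circular mean across legs is taken.
    Legs with no valid phase samples are excluded and reported.
    Returns ``(phase_deg, excluded_legs)``.
    """
    if reference_leg not in phases:
        raise ValueError(f"reference leg {reference_leg!r} has no phase trace")
    ref = np.asarray(phases[reference_leg], dtype=float)
    aligned, excluded = [], []
    for leg, ph in phases.items():
        ph = np.asarray(ph, dtype=float)
        both = np.isfinite(ph) & np.isfinite(ref)
        if not both.any():
            excluded.append(leg)
            continue
        offset = _circ_mean_deg((ph - ref)[both])
        aligned.append((ph - offset) % 360.0)
    stack = np.stack(aligned, axis=0)
    ang = np.radians(stack)
    finite = np.isfinite(ang)
    counts = finite.sum(axis=0)
    s = np.where(finite, np.sin(ang), 0.0).sum(axis=0)
    c = np.where(finite, np.cos(ang), 0.0).sum(axis=0)
    out = np.degrees(np.arctan2(s, c)) % 360.0
    out[counts == 0] = np.nan
    return out, excluded


def spike_phase_profile(
    spike_times: np.ndarray,
    phase: np.ndarray,
    time: np.ndarray,
    walking_mask: np.ndarray,
    offset: float = 0.1,
    n_bins: int = 72,
) -> PhaseProfile:
    """Stride-phase spike histogram, occupancy-normalized and mean-removed.

    Every spike emitted while the fly is walking is assigned to the phase bin
    of the common stride phase read ``offset`` seconds before the spike
    (nearest sample); the per-bin spike count is divided by the occupancy
    (time walking frames spent at that phase, read with the same offset) and
    the occupancy-weighted mean rate is subtracted. Bins with zero occupancy
    get NaN modulation.
    """
    t = np.asarray(time, dtype=float)
    ph = np.asarray(phase, dtype=float) % 360.0
    walking = np.asarray(walking_mask, dtype=bool)
    dt = float(np.median(np.diff(t)))
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    shift = int(round(offset / dt))

    # occupancy: each walking frame contributes dt at the phase `offset` earlier
    fr = np.arange(len(t))
    src = fr - shift
    ok = walking & (src >= 0)
    ph_occ = ph[src[ok]]
    occ_ok = np.isfinite(ph_occ)
    occ_idx = np.clip(np.digitize(ph_occ[occ_ok], edges) - 1, 0, n_bins - 1)
    occupancy = np.bincount(occ_idx, minlength=n_bins) * dt

    spikes = np.asarray(spike_times, dtype=float)
    sp_frame = np.clip(np.round((spikes - t[0]) / dt).astype(int), 0, len(t) - 1)
    keep = walking[sp_frame] & (sp_frame - shift >= 0)
    ph_sp = ph[sp_frame[keep] - shift]
    sp_ok = np.isfinite(ph_sp)
    sp_idx = np.clip(np.digitize(ph_sp[sp_ok], edges) - 1, 0, n_bins - 1)
    counts = np.bincount(sp_idx, minlength=n_bins)

    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occupancy > 0, counts / occupancy, np.nan)
    total_occ = occupancy.sum()
    mean_rate = counts.sum() / total_occ if total_occ > 0 else np.nan
    modulation = rate - mean_rate
    return PhaseProfile(
        bin_edges=edges,
        rate_modulation=modulation,
        occupancy=occupancy,
        offset=offset,
        n_spikes=int(sp_ok.sum()),
    )


def phase_modulation_depth(profile: PhaseProfile):
    """Depth and preferred phase of the first circular harmonic of a profile.

    Occupancy-weighted least-squares fit of
    ``a0 + d cos(theta - theta0)`` to the per-bin modulation; returns
    ``(d, theta0_deg)``. Unlike a plain harmonic projection, the regression
    is exact for a sinusoidal modulation even when the occupied phase
    support is discrete or nonuniform (as for a perfectly regular gait
    sampled at a commensurate frame rate).
    """
    theta = np.radians(profile.bin_centers)
    mod = profile.rate_modulation
    w = profile.occupancy
    good = np.isfinite(mod) & (w > 0)
    if good.sum() < 3:
        return np.nan, np.nan
    X = np.stack([np.ones(good.sum()), np.cos(theta[good]), np.sin(theta[good])], axis=1)
    sw = np.sqrt(w[good])
    coef, *_ = np.linalg.lstsq(X * sw[:, None], mod[good] * sw, rcond=None)
    depth = float(np.hypot(coef[1], coef[2]))
    pref = float(np.degrees(np.arctan2(coef[2], coef[1])) % 360.0)
    return depth, pref


def forward_stepping_mask(continuum: dict, legs=("L2", "L3", "R2", "R3"), tol_deg: float = 90.0):
    """Mask of frames where the middle and hind legs are stepping forward.

    A leg is stepping forward when its continuous step direction is within
    ``tol_deg`` of a straight-backward power stroke (0 deg in the side-signed
    convention). All listed legs must qualify.
    """
    masks = []
    for leg in legs:
        cont = continuum[leg]
        d = np.asarray(cont.step_direction_deg, dtype=float)
        ok = np.abs((d + 180.0) % 360.0 - 180.0) <= tol_deg
        if cont.valid is not None:
            ok &= cont.valid
        masks.append(ok)
    return np.logical_and.reduce(masks)
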