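"""Neural preprocessing: spike detection, firing rate, ratiometric dF/F.

Spike times come from threshold crossings in the derivative of the membrane
potential with a 2-ms refractory exclusion; instantaneous rate is the inverse
interspike interval. Calcium traces are bleach-corrected with a
double-exponential fit per channel and the green (indicator) channel is
normalized ratiometrically to the red (reference) channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

REFRACTORY_S = 0.002

__all__ = [
    "SpikeTrain",
    "RateTrace",
    "FluorescenceTrace",
    "DffTrace",
    "detect_spikes",
    "spike_rate",
    "normalize_rate",
    "fit_double_exponential",
    "compute_dff",
    "bilateral_signals",
]


@dataclass
class SpikeTrain:
    spike_times: np.ndarray      # s, strictly increasing, ISIs >= 2 ms
    source_rate: float = None    # Hz of the voltage trace the spikes came from

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        d = np.diff(self.spike_times)
        if np.any(d <= 0):
            raise ValueError("spike_times must be strictly increasing")

    def __len__(self):
        return len(self.spike_times)


@dataclass
class RateTrace:
    times: np.ndarray
    rate: np.ndarray             # Hz (or dimensionless once normalized)
    normalized: bool = False
    baseline_hz: float = None    # not-walking mean subtracted
    scale_hz: float = None       # 95th-percentile divisor

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.times.shape != self.rate.shape:
            raise ValueError("times and rate must have the same shape")
        if not self.normalized and np.any(self.rate < 0):
            raise ValueError("raw rate must be non-negative")
        if self.normalized and (self.baseline_hz is None or self.scale_hz is None):
            raise ValueError("normalized traces must carry their normalization constants")


@dataclass
class FluorescenceTrace:
    times: np.ndarray
    F: np.ndarray
    channel: str = "green"
    background: object = 0.0     # scalar or per-frame series already in F's units

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if not np.all(np.isfinite(self.F)):
            raise ValueError("fluorescence values must be finite")

    def background_subtracted(self) -> np.ndarray:
        return self.F - np.asarray(self.background, dtype=float)


@dataclass
class DffTrace:
    times: np.ndarray
    dff: np.ndarray
    f0_fit_params: dict = field(default_factory=dict)   # per channel: (a1, tau1, a2, tau2[, offset])


def detect_spikes(
    vm: np.ndarray,
    rate: float,
    dvdt_threshold: float,
    times: np.ndarray = None,
    refractory_s: float = REFRACTORY_S,
) -> SpikeTrain:
    """Spike times from upward threshold crossings of dV/dt.

    dV/dt is computed by central differences on the (already low-pass
    filtered) voltage. Crossings less than ``refractory_s`` after the prior
    accepted crossing are excluded.
    """
    vm = np.asarray(vm, dtype=float)
    if times is not None:
        dt = np.diff(np.asarray(times, dtype=float))
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("voltage trace must be uniformly sampled")
        rate = 1.0 / dt[0]
        t0 = times[0]
    else:
        t0 = 0.0
    dvdt = np.gradient(vm) * rate
    up = np.flatnonzero((dvdt[:-1] < dvdt_threshold) & (dvdt[1:] >= dvdt_threshold)) + 1
    accepted = []
    last = -np.inf
    for i in up:
        t = t0 + i / rate
        if t - last >= refractory_s:
            accepted.append(t)
            last = t
    return SpikeTrain(spike_times=np.asarray(accepted), source_rate=rate)


def spike_rate(train: SpikeTrain, eval_times: np.ndarray, outside: str = "zero") -> RateTrace:
    """Instantaneous firing rate as the inverse interspike interval.

    The rate over each interspike interval ``(t_k, t_{k+1}]`` is ``1/ISI``;
    outside the first/last spike the rate is 0 (``outside='zero'``) or holds
    the nearest interval's value (``outside='hold'``).
    """
    t = np.asarray(eval_times, dtype=float)
    spikes = train.spike_times
    if len(spikes) < 2:
        return RateTrace(times=t, rate=np.zeros_like(t))
    isi_rate = 1.0 / np.diff(spikes)
    # interval index for each eval time: spikes[i] < t <= spikes[i+1]
    idx = np.searchsorted(spikes, t, side="left") - 1
    inside = (idx >= 0) & (idx < len(isi_rate))
    r = np.zeros_like(t)
    r[inside] = isi_rate[idx[inside]]
    if outside == "hold":
        r[idx < 0] = isi_rate[0]
        r[idx >= len(isi_rate)] = isi_rate[-1]
    r[t == spikes[0]] = isi_rate[0]
    return RateTrace(times=t, rate=r)


def normalize_rate(rate: RateTrace, walking_mask: np.ndarray) -> RateTrace:
    """Normalize a rate trace to the fly's own dynamic range.

    Subtracts the mean rate when the fly was not walking and divides by the
    95th percentile of the mean-subtracted distribution (over all samples).
    """
    mask = np.asarray(walking_mask, dtype=bool)
    if mask.shape != rate.rate.shape:
        raise ValueError("walking_mask must align with the rate samples")
    if not np.any(~mask):
        raise ValueError(
            "no not-walking samples to define the baseline; supply a baseline epoch"
        )
    baseline = float(np.mean(rate.rate[~mask]))
    resid = rate.rate - baseline
    scale = float(np.percentile(resid, 95))
    if scale <= 0:
        raise ValueError("95th percentile of the residual rate is not positive")
    return RateTrace(
        times=rate.times,
        rate=resid / scale,
        normalized=True,
        baseline_hz=baseline,
        scale_hz=scale,
    )


def _double_exp(t, a1, tau1, a2, tau2, offset=0.0):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + offset


def _loglinear_tau(t, f):
    """Crude (tau, amplitude) from a log-linear fit; assumes f > 0."""
    good = f > 0
    if good.sum() < 2:
        return None
    p = np.polyfit(t[good], np.log(f[good]), 1)
    slope, intercept = p[0], p[1]
    if slope >= 0:
        return None
    return -1.0 / slope, float(np.exp(intercept))


def fit_double_exponential(
    times: np.ndarray, f: np.ndarray, with_offset: bool = False, trim_iters: int = 2,
    trim_nsigma: float = 2.5,
):
    """Least-squares fit of ``a1 exp(-t/tau1) + a2 exp(-t/tau2)`` to a trace.

    Initialization is deterministic: the slow component comes from a
    log-linear fit to the second half of the trace, the fast component from a
    log-linear fit of the early residual. After the first fit, samples whose
    residual exceeds ``trim_nsigma`` robust standard deviations (MAD-based)
    are excluded and the fit repeated (``trim_iters`` times), so brief
    signal transients riding on the bleach envelope do not bias the
    baseline. Returns the parameter dict and the fitted curve evaluated on
    the full trace.
    """
    t = np.asarray(times, dtype=float) - times[0]
    f = np.asarray(f, dtype=float)
    span = t[-1] if t[-1] > 0 else 1.0

    slow = _loglinear_tau(t[len(t) // 2 :], f[len(t) // 2 :])
    if slow is None:
        slow = (span, max(float(np.mean(f[len(t) // 2 :])), 1e-12))
    tau2, a2 = slow
    resid = f - a2 * np.exp(-t / tau2)
    n_early = max(len(t) // 10, 2)
    fast = _loglinear_tau(t[:n_early], resid[:n_early])
    if fast is None:
        tau1, a1 = span / 20.0, max(float(resid[0]), 1e-3 * a2)
    else:
        tau1, a1 = fast
    tau1 = min(max(tau1, 1e-6), span)
    tau2 = min(max(tau2, 1e-6), 100 * span)

    if with_offset:
        x0 = [a1, tau1, a2, tau2, 0.0]
        lb = [0.0, 1e-9, 0.0, 1e-9, -np.inf]
        names = ("a1", "tau1", "a2", "tau2", "offset")
    else:
        x0 = [a1, tau1, a2, tau2]
        lb = [0.0, 1e-9, 0.0, 1e-9]
        names = ("a1", "tau1", "a2", "tau2")
    ub = [np.inf] * len(x0)

    keep = np.ones(len(t), dtype=bool)
    res = None
    for _ in range(trim_iters + 1):
        fun = lambda p, k=keep: _double_exp(t[k], *p) - f[k]
        res = least_squares(fun, x0, bounds=(lb, ub), method="trf", max_nfev=5000)
        if not res.success and res.status <= 0:
            raise RuntimeError(f"double-exponential fit failed: {res.message}")
        x0 = res.x
        resid = f - _double_exp(t, *res.x)
        mad = np.median(np.abs(resid[keep] - np.median(resid[keep])))
        if mad <= 0:
            break
        new_keep = np.abs(resid) <= trim_nsigma * 1.4826 * mad
        if new_keep.sum() < max(10, len(t) // 4) or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    params = dict(zip(names, (float(v) for v in res.x)))
    fitted = _double_exp(t, *res.x)
    return params, fitted


def compute_dff(
    green: FluorescenceTrace, red: FluorescenceTrace, with_offset: bool = False
) -> DffTrace:
    """Ratiometric dF/F with per-channel double-exponential bleach correction.

    Each background-subtracted channel is fit with a sum of two exponentials;
    F(t)/F0(t) uses the fitted value as F0 at every time. The indicator
    signal is then normalized to the reference channel:
    ``dff = (green F/F0) / (red F/F0) - 1``.
    """
    if len(green.F) != len(red.F):
        raise ValueError("green and red traces must be aligned")
    out_params = {}
    ratios = {}
    for tr in (green, red):
        f = tr.background_subtracted()
        params, f0 = fit_double_exponential(tr.times, f, with_offset=with_offset)
        if np.any(f0 <= 0):
            raise RuntimeError(
                f"{tr.channel} channel bleach fit is non-positive somewhere; "
                f"fit parameters: {params}"
            )
        out_params[tr.channel] = params
        ratios[tr.channel] = f / f0
    dff = ratios[green.channel] / ratios[red.channel] - 1.0
    return DffTrace(times=np.asarray(green.times, dtype=float), dff=dff, f0_fit_params=out_params)


def bilateral_signals(left: DffTrace, right: DffTrace):
    """Right-left difference and right+left sum of two aligned dF/F traces."""
    if len(left.dff) != len(right.dff):
        raise ValueError("left and right traces must be aligned")
    return right.dff - left.dff, right.dff + left.dff
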