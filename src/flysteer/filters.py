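"""First-order Wiener kernels linking neural signals to behavior.

Two estimators of the linear filter between an input series (e.g. a neural
signal) and a response series (e.g. rotational velocity):

* :func:`wiener_fft` - frequency-domain ratio ``conj(I) R / (conj(I) I + eps)``
  on the full series, used for slow calcium signals;
* :func:`wiener_xcorr` - ratio of the Fourier transforms of the lagged
  Pearson cross-correlation and the input autocorrelation (computed on a
  +-1 s, 1-ms lag grid), used for spike rates.

Both apply the same soft spectral low-pass
``c(w) = exp(-(|w| - f_cut)/f_tau)`` for ``|w| >= f_cut`` (1 below f_cut) and
store lags so that NEGATIVE lags mean the input precedes the response; a
neural signal that drives behavior 100 ms later yields a filter peaking at
-0.1 s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _signal

__all__ = [
    "FilterConfig",
    "LinearFilter",
    "wiener_fft",
    "wiener_xcorr",
    "peak_time",
    "lagged_pearson",
    "autocorr_fwhm",
]


@dataclass
class FilterConfig:
    f_cut: float = 4.0           # Hz; unity gain below this frequency
    f_tau: float = 1.0           # Hz; exponential roll-off scale above f_cut
    max_lag: float = 1.0         # s
    lag_step: float = None       # s; defaults to the sample interval (fft) or 1 ms (xcorr)
    variant: str = "fft_ratio"
    eps_scale: float = 1e-6      # regularizer relative to mean input power
    peak_edge_fraction: float = 0.05
    peak_rel_height: float = 0.10

    def __post_init__(self):
        if self.f_cut <= 0 or self.f_tau <= 0:
            raise ValueError("f_cut and f_tau must be positive")


# standard defaults: calcium analyses use (4 Hz, 1 Hz), spike analyses (2 Hz, 0.5 Hz)
CALCIUM_CONFIG = FilterConfig(f_cut=4.0, f_tau=1.0, variant="fft_ratio")
SPIKE_CONFIG = FilterConfig(f_cut=2.0, f_tau=0.5, variant="xcorr")


@dataclass
class LinearFilter:
    lags: np.ndarray             # s, uniform; negative = input precedes response
    values: np.ndarray
    config: FilterConfig = None
    valid: bool = True

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must align")

    @property
    def peak_time(self) -> float:
        return peak_time(self)

    @property
    def lag_step(self) -> float:
        return float(np.median(np.diff(self.lags)))


def peak_time(filt: LinearFilter) -> float:
    """Lag of the filter's global maximum; ties break toward smaller |lag|."""
    if not filt.valid:
        raise ValueError("filter is flagged invalid; no defined peak")
    v = filt.values
    vmax = v.max()
    tol = 1e-12 * max(1.0, abs(vmax))
    cand = np.flatnonzero(v >= vmax - tol)
    best = cand[np.argmin(np.abs(filt.lags[cand]))]
    return float(filt.lags[best])


def _lowpass_weights(freqs: np.ndarray, f_cut: float, f_tau: float) -> np.ndarray:
    w = np.ones_like(freqs)
    m = np.abs(freqs) >= f_cut
    w[m] = np.exp(-(np.abs(freqs[m]) - f_cut) / f_tau)
    return w


def _check_peak_defined(lags, values, cfg: FilterConfig) -> bool:
    """A 'defined peak': global max clear of the edges and above edge values."""
    n = len(values)
    edge = max(1, int(round(cfg.peak_edge_fraction * n)))
    imax = int(np.argmax(values))
    if imax < edge or imax >= n - edge:
        return False
    rng = values.max() - values.min()
    if rng <= 0:
        return False
    edge_val = max(values[0], values[-1])
    return values[imax] - edge_val >= cfg.peak_rel_height * rng


def wiener_fft(inp: np.ndarray, resp: np.ndarray, rate: float, config: FilterConfig = None) -> LinearFilter:
    """First-order Wiener kernel via the FFT ratio on the full series.

    ``F(w) = conj(I) R / (conj(I) I + eps)`` with ``eps`` a small fraction of
    the mean input power, then the soft low-pass ``c(w)``, then the inverse
    transform. Input and response must be aligned and uniformly sampled at
    ``rate`` (for calcium analyses, interpolate to 100 Hz first).
    """
    cfg = config if config is not None else replace(CALCIUM_CONFIG)
    x = np.asarray(inp, dtype=float)
    y = np.asarray(resp, dtype=float)
    if x.shape != y.shape:
        raise ValueError("input and response must be the same length")
    if np.std(x) == 0:
        raise ValueError("zero-variance input")
    x = x - x.mean()
    y = y - y.mean()
    n = len(x)
    X = np.fft.fft(x)
    Y = np.fft.fft(y)
    power = np.conj(X) * X
    eps = cfg.eps_scale * float(np.mean(power.real))
    F = np.conj(X) * Y / (power.real + eps)
    freqs = np.fft.fftfreq(n, d=1.0 / rate)
    F *= _lowpass_weights(freqs, cfg.f_cut, cfg.f_tau)
    h = np.real(np.fft.ifft(F)) * rate          # impulse response per unit input, 1/s units folded in
    h = np.fft.fftshift(h)
    u = (np.arange(n) - n // 2) / rate          # causal lag axis: response lags input at u > 0
    keep = np.abs(u) <= cfg.max_lag + 1e-12
    u, h = u[keep], h[keep]
    lags = -u[::-1]
    values = h[::-1]
    valid = _check_peak_defined(lags, values, cfg)
    return LinearFilter(lags=lags, values=values, config=cfg, valid=valid)


def lagged_pearson(x: np.ndarray, y: np.ndarray, max_lag_samples: int, normalization: str = "biased"):
    """Pearson correlation of ``x(t)`` with ``y(t + u)`` for each lag ``u``.

    Uses global means and standard deviations. ``normalization='biased'``
    divides every lag by the full series length (Bartlett-windowed
    correlogram): values at lag ``u`` are shrunk by ``1 - |u|/n`` (< 1% for
    the +-1 s window on minutes of data) but the implied autocorrelation
    spectrum stays positive semidefinite, which keeps the Wiener spectral
    ratio stable. ``'unbiased'`` divides by the per-lag overlap count.
    Returns ``(lags_samples, r)``; a peak at positive ``u`` means the
    response ``y`` lags the input ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("series must be the same length")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance series; correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    c = _signal.correlate(yc, xc, mode="full", method="fft")
    lags = np.arange(-(n - 1), n)
    denom = float(n) if normalization == "biased" else (n - np.abs(lags))
    r = c / (denom * sx * sy)
    keep = np.abs(lags) <= max_lag_samples
    return lags[keep], r[keep]


def _resample(x: np.ndarray, rate: float, out_rate: float) -> np.ndarray:
    if abs(rate - out_rate) < 1e-9:
        return np.asarray(x, dtype=float)
    t_in = np.arange(len(x)) / rate
    t_out = np.arange(0.0, t_in[-1] + 0.5 / out_rate, 1.0 / out_rate)
    return np.interp(t_out, t_in, np.asarray(x, dtype=float))


def wiener_xcorr(inp: np.ndarray, resp: np.ndarray, rate: float, config: FilterConfig = None) -> LinearFilter:
    """First-order Wiener kernel from lagged correlations (spike-rate variant).

    Both series are resampled to the lag grid (1 kHz by default so the 1-ms
    lag increments are exact); the lagged Pearson cross-correlation and the
    input autocorrelation over +-max_lag are Fourier-transformed, divided,
    soft low-passed by ``c(w)`` and transformed back. Filters whose maximum
    is not a defined interior peak are flagged invalid.
    """
    cfg = config if config is not None else replace(SPIKE_CONFIG)
    lag_step = cfg.lag_step if cfg.lag_step is not None else 0.001
    grid_rate = 1.0 / lag_step
    x = _resample(inp, rate, grid_rate)
    y = _resample(resp, rate, grid_rate)
    m = int(round(cfg.max_lag / lag_step))
    _, rxy = lagged_pearson(x, y, m)
    _, rxx = lagged_pearson(x, x, m)
    nlag = 2 * m + 1
    Fxy = np.fft.fft(np.fft.ifftshift(rxy))
    Fxx = np.fft.fft(np.fft.ifftshift(rxx))
    eps = cfg.eps_scale * float(np.mean(np.abs(Fxx)))
    H = Fxy / (Fxx + eps)
    freqs = np.fft.fftfreq(nlag, d=lag_step)
    H *= _lowpass_weights(freqs, cfg.f_cut, cfg.f_tau)
    # Pearson-normalized correlations leave a sigma_x/sigma_y factor in the
    # ratio; undo it so values are response-units per input-unit, and scale
    # to a density like wiener_fft
    h = np.fft.fftshift(np.real(np.fft.ifft(H))) * (y.std() / x.std()) * grid_rate
    u = (np.arange(nlag) - m) * lag_step
    lags = -u[::-1]
    values = h[::-1]
    valid = _check_peak_defined(lags, values, cfg)
    return LinearFilter(lags=lags, values=values, config=cfg, valid=valid)


def autocorr_fwhm(x: np.ndarray, rate: float, max_lag: float = 1.0, lag_step: float = 0.001) -> float:
    """Full width at half maximum of the lagged Pearson autocorrelation.

    The autocorrelation is computed at 1-ms lags over +-1 s; the FWHM is the
    duration of the contiguous window around lag 0 where r >= 0.5, with
    sub-sample boundaries by linear interpolation.
    """
    grid_rate = 1.0 / lag_step
    xs = _resample(x, rate, grid_rate)
    m = int(round(max_lag / lag_step))
    lags, r = lagged_pearson(xs, xs, m)
    i0 = m  # lag 0
    # walk outward to the first crossings below 0.5
    def _edge(direction):
        i = i0
        while 0 <= i + direction < len(r) and r[i + direction] >= 0.5:
            i += direction
        j = i + direction
        if j < 0 or j >= len(r):
            return abs(i - i0) * lag_step
        # linear interpolation between r[i] (>= 0.5) and r[j] (< 0.5)
        frac = (r[i] - 0.5) / (r[i] - r[j])
        return (abs(i - i0) + frac) * lag_step

    return _edge(-1) + _edge(+1)
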