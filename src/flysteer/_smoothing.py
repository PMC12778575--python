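"""Gaussian-weighted moving averages shared across the pipeline.

All behavioral traces in this package are smoothed with a truncated-Gaussian
moving average parameterized by its full window width. The kernel standard
deviation is ``window / 5`` and the kernel is truncated at ``+-window / 2``
and renormalized to unit sum, so constants pass through exactly. At trace
edges the kernel is renormalized over the available samples (no padding),
which keeps bout edges free of fabricated data.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gaussian_kernel", "gaussian_smooth"]


def gaussian_kernel(window_samples: float) -> np.ndarray:
    """Unit-sum truncated Gaussian kernel for a full window of ``window_samples``.

    sigma = window / 5; support = ``2 * floor(window / 2) + 1`` samples.
    """
    if window_samples <= 0:
        raise ValueError("window must be positive")
    half = int(np.floor(window_samples / 2))
    if half < 1:
        return np.ones(1)
    k = np.arange(-half, half + 1, dtype=float)
    sigma = window_samples / 5.0
    w = np.exp(-0.5 * (k / sigma) ** 2)
    return w / w.sum()


def gaussian_smooth(x: np.ndarray, window_samples: float) -> np.ndarray:
    """Smooth ``x`` (1-D) with a Gaussian-weighted moving average.

    Edge samples are renormalized over the in-range part of the kernel.
    """
    x = np.asarray(x, dtype=float)
    w = gaussian_kernel(window_samples)
    if w.size == 1 or x.size == 0:
        return x.copy()
    num = np.convolve(x, w, mode="same")
    den = np.convolve(np.ones_like(x), w, mode="same")
    return num / den
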