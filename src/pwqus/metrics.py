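"""Image-quality metrics used to monitor reconstruction training.

MNAE (mean normalized absolute error) follows the convention of absolute
error normalized by the target dynamic range.  PSNR and SSIM follow the
textbook definitions (SSIM with a 7 x 7 uniform window, sample-covariance
normalization and K1 = 0.01, K2 = 0.03).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = ["mnae", "psnr", "ssim"]


def mnae(pred: np.ndarray, target: np.ndarray, data_range: float | None = None) -> float:
    """Mean absolute error normalized by the target dynamic range."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if data_range is None:
        data_range = float(target.max() - target.min())
        if data_range == 0:
            data_range = 1.0
    return float(np.mean(np.abs(pred - target)) / data_range)


def psnr(pred: np.ndarray, target: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB."""
    mse = float(np.mean((np.asarray(pred, float) - np.asarray(target, float)) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def ssim(
    pred: np.ndarray,
    target: np.ndarray,
    data_range: float = 1.0,
    win_size: int = 7,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Structural similarity index over a uniform sliding window."""
    x = np.asarray(target, dtype=np.float64)
    y = np.asarray(pred, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    np_pix = win_size**x.ndim
    cov_norm = np_pix / (np_pix - 1)
    filt = lambda a: uniform_filter(a, size=win_size)
    ux, uy = filt(x), filt(y)
    uxx, uyy, uxy = filt(x * x), filt(y * y), filt(x * y)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux**2 + uy**2 + c1) * (vx + vy + c2)
    )
    pad = (win_size - 1) // 2
    crop = tuple(slice(pad, d - pad) for d in s.shape)
    return float(s[crop].mean())
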