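"""Independent brute-force metric implementations used as test oracles.

Deliberately naive (explicit per-window loops, float64) and written
directly from the metric definitions, so they share no code with the
package implementations they check.
"""

from __future__ import annotations

import numpy as np


def gaussian_kernel(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim_brute_force(a: np.ndarray, b: np.ndarray, window: int = 11,
                     sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03,
                     data_range: float = 255.0) -> float:
    """Mean SSIM over all fully interior Gaussian-weighted windows.

    Per-channel evaluation averaged for color inputs.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.ndim == 3:
        return float(np.mean([
            ssim_brute_force(a[..., c], b[..., c], window, sigma, k1, k2, data_range)
            for c in range(a.shape[2])
        ]))
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    w = gaussian_kernel(window, sigma)
    half = window // 2
    h, wd = a.shape
    values = []
    for i in range(half, h - half):
        for j in range(half, wd - half):
            wa = a[i - half : i + half + 1, j - half : j + half + 1]
            wb = b[i - half : i + half + 1, j - half : j + half + 1]
            ua = (w * wa).sum()
            ub = (w * wb).sum()
            va = (w * wa * wa).sum() - ua * ua
            vb = (w * wb * wb).sum() - ub * ub
            cov = (w * wa * wb).sum() - ua * ub
            s = ((2 * ua * ub + c1) * (2 * cov + c2)) / ((ua * ua + ub * ub + c1) * (va + vb + c2))
            values.append(s)
    return float(np.mean(values))


def psnr_brute_force(a: np.ndarray, b: np.ndarray, data_range: float = 255.0) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    mse = np.mean((a - b) ** 2)
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(data_range ** 2 / mse))
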