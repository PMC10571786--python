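"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths (and scipy's
separable filtering) so they can serve as ground truth.
"""

from __future__ import annotations

import math

import numpy as np

SSIM_SIGMA = 1.5
SSIM_RADIUS = 5  # 11x11 window
SSIM_K1, SSIM_K2 = 0.01, 0.03


def gaussian_window(radius: int = SSIM_RADIUS, sigma: float = SSIM_SIGMA) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    k /= k.sum()
    return np.outer(k, k)


def naive_ssim(a: np.ndarray, b: np.ndarray, data_range: float = 255.0) -> float:
    """Windowed SSIM by explicit double loop over all full-window positions."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    assert a.shape == b.shape and a.ndim == 2
    w = gaussian_window()
    r = SSIM_RADIUS
    c1 = (SSIM_K1 * data_range) ** 2
    c2 = (SSIM_K2 * data_range) ** 2
    values = []
    for i in range(r, a.shape[0] - r):
        for j in range(r, a.shape[1] - r):
            wa = a[i - r : i + r + 1, j - r : j + r + 1]
            wb = b[i - r : i + r + 1, j - r : j + r + 1]
            mu_a = float((w * wa).sum())
            mu_b = float((w * wb).sum())
            var_a = float((w * wa * wa).sum()) - mu_a * mu_a
            var_b = float((w * wb * wb).sum()) - mu_b * mu_b
            cov = float((w * wa * wb).sum()) - mu_a * mu_b
            values.append(
                ((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
            )
    return float(np.mean(values))


def two_pass_channel_stats(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Population mean/std per channel via an explicit two-pass loop."""
    pixels = np.asarray(pixels, dtype=np.float64).reshape(-1, 3)
    n = pixels.shape[0]
    mean = np.zeros(3)
    for p in pixels:
        mean += p
    mean /= n
    acc = np.zeros(3)
    for p in pixels:
        acc += (p - mean) ** 2
    return mean, np.sqrt(acc / n)


def shannon_entropy_bits(levels: np.ndarray) -> float:
    """Entropy of integer gray levels by explicit counting."""
    counts: dict[int, int] = {}
    for v in np.asarray(levels).ravel():
        counts[int(v)] = counts.get(int(v), 0) + 1
    n = sum(counts.values())
    return -sum((c / n) * math.log2(c / n) for c in counts.values())
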