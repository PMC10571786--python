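"""Three-metric evaluation of WLI / simulated-NBI pairs.

SSIM (structural similarity), PSNR, and Shannon histogram entropy (with
the absolute entropy difference between the two frames). All three
operate on the BT.601 grayscale luminance of unit-range RGB images, on
an 8-bit (0–255) dynamic range.

SSIM uses the standard Wang et al. configuration: Gaussian window
(σ = 1.5, 11×11 support), K1 = 0.01, K2 = 0.03, population-weighted
window covariances. PSNR is 10·log10(255²/MSE) over all channels with a
``+inf`` sentinel for identical images. Entropy is the Shannon entropy
of the 256-bin grayscale histogram, in bits (0·log 0 := 0), so it lies
in [0, 8].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

#: ITU-R BT.601 luma weights.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Minimum image side for the 11×11 SSIM window.
SSIM_WIN_SIZE = 11


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"image dimensions differ: {a.shape} vs {b.shape}")
    return a, b


def luminance(rgb: np.ndarray) -> np.ndarray:
    """BT.601 grayscale luminance on the 0–255 scale."""
    arr = np.asarray(rgb, dtype=np.float64)
    if arr.ndim == 2:
        return arr * 255.0
    return (arr @ LUMA_WEIGHTS) * 255.0


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean local SSIM between two images, in [−1, 1].

    Images are converted to grayscale luminance first; the windowed
    statistics use a Gaussian weighting (σ = 1.5) and the standard
    stabilization constants, so identical images score exactly 1.
    """
    a, b = _check_pair(a, b)
    ga, gb = luminance(a), luminance(b)
    if min(ga.shape) < SSIM_WIN_SIZE:
        raise ValueError(
            f"image sides must be at least {SSIM_WIN_SIZE} pixels, got {ga.shape}"
        )
    return float(
        structural_similarity(
            ga,
            gb,
            data_range=255.0,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def psnr(a: np.ndarray, b: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB on the 8-bit scale.

    Computed over all three channels; identical images return ``inf``.
    """
    a, b = _check_pair(a, b)
    mse = float(np.mean(((a - b) * 255.0) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(255.0**2 / mse)


def entropy(img: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin grayscale histogram."""
    gray = luminance(img)
    if gray.size == 0:
        raise ValueError("image is empty")
    levels = np.clip(np.rint(gray), 0, 255).astype(np.intp)
    counts = np.bincount(levels.ravel(), minlength=256)
    p = counts[counts > 0] / levels.size
    return float(-np.sum(p * np.log2(p)))


def entropy_difference(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute difference of the two images' histogram entropies, in bits."""
    return abs(entropy(a) - entropy(b))


@dataclass(frozen=True)
class MetricReport:
    """All three metrics for one WLI / simulated-NBI pair.

    ``ssim`` is stored in [−1, 1]; user-facing output uses
    :attr:`ssim_pct`. ``entropy_wli`` / ``entropy_nbi`` are in bits.
    """

    image_id: str
    ssim: float
    psnr_db: float
    entropy_wli: float
    entropy_nbi: float

    @property
    def entropy_diff(self) -> float:
        return abs(self.entropy_wli - self.entropy_nbi)

    @property
    def ssim_pct(self) -> float:
        return 100.0 * self.ssim

    @property
    def entropy_diff_pct(self) -> float:
        """Entropy difference relative to the WLI entropy, in percent."""
        if self.entropy_wli == 0.0:
            return 0.0 if self.entropy_diff == 0.0 else float("inf")
        return 100.0 * self.entropy_diff / self.entropy_wli


def evaluate_pair(wli: np.ndarray, nbi_sim: np.ndarray, image_id: str = "") -> MetricReport:
    """Compute SSIM, PSNR and entropies for one WLI / simulated-NBI pair."""
    wli, nbi_sim = _check_pair(wli, nbi_sim)
    return MetricReport(
        image_id=image_id,
        ssim=ssim(wli, nbi_sim),
        psnr_db=psnr(wli, nbi_sim),
        entropy_wli=entropy(wli),
        entropy_nbi=entropy(nbi_sim),
    )
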