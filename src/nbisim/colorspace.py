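"""Transforms between display RGB, LMS cone space, log-LMS, and lαβ.

The conversion chain used throughout the package is

    RGB (unit range) --> LMS cone responses --> log10 LMS --> lαβ

and its inverse. Images are plain ``float64`` numpy arrays of shape
``(H, W, 3)``; RGB arrays are in the unit range ``[0, 1]`` (byte images
are divided by 255 at the I/O boundary, see :mod:`nbisim.io`).

The RGB→LMS map is a single 3×3 matrix (the combined ITU tristimulus /
cone-fundamental conversion). LMS values are clamped to a small positive
floor before the base-10 logarithm so that black pixels — ubiquitous in
endoscopy frames as border fill — stay finite. The lαβ space is
Ruderman's decorrelated opponent space: an orthogonal, row-scaled linear
map of log-LMS separating an achromatic axis ``l`` from yellow–blue
``α`` and red–green ``β``. Because the map is orthogonal its inverse is
its transpose, so the round trip is exact to floating-point precision.

Inputs are treated as linear RGB; no sRGB gamma linearization is
applied (documented limitation, see ``docs/methods.md``).
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

#: Combined RGB→LMS conversion matrix (applied to (R,G,B) column vectors).
RGB_TO_LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)

#: Inverse of :data:`RGB_TO_LMS`, computed once at import.
LMS_TO_RGB = np.linalg.inv(RGB_TO_LMS)

# Ruderman decorrelation: diag(1/√3, 1/√6, 1/√2) · [[1,1,1],[1,1,-2],[1,-1,0]].
# The row-scaled matrix is orthogonal, so its inverse is its transpose.
_INTEGER_OPPONENT = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, -2.0], [1.0, -1.0, 0.0]])
LOG_TO_LAB = np.diag([1.0 / np.sqrt(3.0), 1.0 / np.sqrt(6.0), 1.0 / np.sqrt(2.0)]) @ _INTEGER_OPPONENT
LAB_TO_LOG = LOG_TO_LAB.T

#: Default clamp applied to LMS values before the logarithm (one byte step).
DEFAULT_LOG_FLOOR = 1.0 / 255.0


def _as_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {arr.shape}")
    return arr


def _apply(matrix: np.ndarray, img: np.ndarray) -> np.ndarray:
    # per-pixel matrix · (c0,c1,c2) column vector
    return _as_image(img) @ matrix.T


def rgb_to_lms(img: np.ndarray) -> np.ndarray:
    """Map a unit-range RGB image to LMS cone responses.

    The transform is linear, so black maps to black and the unit basis
    colors map to the columns of :data:`RGB_TO_LMS`.
    """
    return _apply(RGB_TO_LMS, img)


def lms_to_rgb(img: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_lms`; output is *not* clipped."""
    return _apply(LMS_TO_RGB, img)


def lms_to_log(img: np.ndarray, floor: float = DEFAULT_LOG_FLOOR) -> np.ndarray:
    """Base-10 logarithm of LMS values clamped to ``floor``.

    Parameters
    ----------
    floor:
        Positive clamp applied before the log so zero-valued pixels
        (black borders) produce finite output. Default ``1/255``.
    """
    if not floor > 0:
        raise ValueError(f"floor must be positive, got {floor}")
    arr = _as_image(img)
    return np.log10(np.maximum(arr, floor))


def log_to_lms(img: np.ndarray) -> np.ndarray:
    """Exponentiate log-LMS back to LMS (base 10)."""
    return np.power(10.0, _as_image(img))


def log_to_lab(img: np.ndarray) -> np.ndarray:
    """Decorrelate log-LMS into lαβ:
    l=(L+M+S)/√3, α=(L+M−2S)/√6, β=(L−M)/√2."""
    return _apply(LOG_TO_LAB, img)


def lab_to_log(img: np.ndarray) -> np.ndarray:
    """Inverse decorrelation (transpose of the orthogonal lαβ map)."""
    return _apply(LAB_TO_LOG, img)


def rgb_to_lab(img: np.ndarray, floor: float = DEFAULT_LOG_FLOOR) -> np.ndarray:
    """Full forward chain RGB → LMS → log-LMS → lαβ."""
    return log_to_lab(lms_to_log(rgb_to_lms(img), floor=floor))


def lab_to_rgb(img: np.ndarray, return_clipped_fraction: bool = False):
    """Full inverse chain lαβ → log-LMS → LMS → RGB, clipped to [0, 1].

    Out-of-gamut pixels are clipped rather than raising; the fraction of
    clipped pixels is logged at INFO and optionally returned.

    Returns
    -------
    rgb : ndarray
        Unit-range RGB image.
    clipped_fraction : float, optional
        Fraction of pixels with at least one channel clipped, returned
        when ``return_clipped_fraction`` is true.
    """
    # clamp to ±12 decades before exponentiation: values beyond that are
    # out of gamut regardless, and unbounded exponents would overflow
    log_lms = np.clip(lab_to_log(img), -12.0, 12.0)
    raw = lms_to_rgb(log_to_lms(log_lms))
    clipped = np.any((raw < 0.0) | (raw > 1.0), axis=-1)
    fraction = float(clipped.mean())
    if fraction > 0:
        logger.info("lab_to_rgb clipped %.3f%% of pixels to gamut", 100.0 * fraction)
    rgb = np.clip(raw, 0.0, 1.0)
    if return_clipped_fraction:
        return rgb, fraction
    return rgb
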