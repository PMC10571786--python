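"""Image reading/writing and quantization conventions.

All in-memory computation is on unit-range float64 arrays; byte
conversion happens only here. Writing quantizes once with round-half-up
(``floor(255·x + 0.5)``) after clipping, so a write/read round trip is
byte-exact.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)


def quantize(img: np.ndarray) -> np.ndarray:
    """Clip to [0, 1] and quantize to uint8, rounding half up."""
    arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    return np.floor(arr * 255.0 + 0.5).astype(np.uint8)


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF frame as a unit-range (H, W, 3) float array.

    Grayscale inputs are promoted to three identical channels; an alpha
    channel is dropped with a warning; 16-bit inputs are rescaled by
    65535 with a warning.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # imageio raises various backend errors
        raise IOError(f"cannot read image {path}: {exc}") from exc

    arr = np.asarray(raw)
    if arr.dtype == np.uint16:
        logger.warning("%s: 16-bit input rescaled to unit range", path)
        img = arr.astype(np.float64) / 65535.0
    elif arr.dtype == np.uint8:
        img = arr.astype(np.float64) / 255.0
    elif np.issubdtype(arr.dtype, np.floating):
        img = arr.astype(np.float64)
    else:
        raise IOError(f"cannot read image {path}: unsupported dtype {arr.dtype}")

    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    elif img.ndim == 3 and img.shape[-1] == 4:
        logger.warning("%s: alpha channel discarded", path)
        img = img[..., :3]
    elif img.ndim != 3 or img.shape[-1] != 3:
        raise IOError(f"cannot read image {path}: unexpected shape {arr.shape}")
    return img


def write_image(img: np.ndarray, path) -> None:
    """Write a unit-range image as an 8-bit PNG, creating directories."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        iio.imwrite(path, quantize(img))
    except Exception as exc:
        raise IOError(f"cannot write image {path}: {exc}") from exc
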