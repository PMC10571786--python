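"""Per-axis statistics transfer in lαβ — the core NBI-simulation step.

A white-light (WLI) frame is recolored to look like a narrow-band (NBI)
frame by imposing the NBI reference's per-axis mean and standard
deviation on the WLI frame in the decorrelated lαβ space:

    out = (value − src_mean) · (σ_target / σ_source) + target_mean

applied independently on each of the three axes. Because the axes are
decorrelated, matching first and second moments per axis is enough to
carry the global color character of the reference across.

Statistics use the population (1/N) standard deviation so that the
transfer is exactly idempotent and exactly imposes the target moments.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from . import colorspace

logger = logging.getLogger(__name__)

#: Identifier for the statistics space written into JSON files.
STATS_SPACE = "lab_ruderman_log10"

#: Luminance threshold (unit range) below which the auto border mask
#: excludes pixels — mimics the capsule's circular field-of-view fill.
AUTO_BORDER_THRESHOLD = 10.0 / 255.0


@dataclass(frozen=True)
class ChannelStats:
    """Per-axis mean and population standard deviation of an lαβ image.

    ``mean`` and ``std`` are length-3 arrays ordered (l, α, β);
    ``n_pixels`` is the number of pixels the statistics were computed
    over (after masking).
    """

    mean: np.ndarray
    std: np.ndarray
    n_pixels: int

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=np.float64).reshape(3)
        std = np.asarray(self.std, dtype=np.float64).reshape(3)
        if np.any(std < 0):
            raise ValueError("standard deviations must be nonnegative")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be positive")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "std", std)

    def to_dict(self) -> dict:
        return {
            "space": STATS_SPACE,
            "mean": [float(v) for v in self.mean],
            "std": [float(v) for v in self.std],
            "n_pixels": int(self.n_pixels),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, data: dict) -> "ChannelStats":
        space = data.get("space", STATS_SPACE)
        if space != STATS_SPACE:
            raise ValueError(f"unsupported statistics space {space!r}")
        return cls(
            mean=np.asarray(data["mean"], dtype=np.float64),
            std=np.asarray(data["std"], dtype=np.float64),
            n_pixels=int(data["n_pixels"]),
        )

    @classmethod
    def from_json(cls, text: str) -> "ChannelStats":
        return cls.from_dict(json.loads(text))


def save_stats(stats: ChannelStats, path) -> None:
    Path(path).write_text(stats.to_json())


def load_stats(path) -> ChannelStats:
    return ChannelStats.from_json(Path(path).read_text())


def _masked_pixels(img: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {arr.shape}")
    if mask is None:
        return arr.reshape(-1, 3)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != arr.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {arr.shape[:2]}"
        )
    if mask.sum() < 2:
        raise ValueError("mask must select at least 2 pixels (std undefined otherwise)")
    return arr[mask]


def compute_stats(img: np.ndarray, mask: np.ndarray | None = None) -> ChannelStats:
    """Per-axis mean and population std of an lαβ image over masked pixels."""
    pixels = _masked_pixels(img, mask)
    return ChannelStats(
        mean=pixels.mean(axis=0),
        std=pixels.std(axis=0),  # population (ddof=0)
        n_pixels=pixels.shape[0],
    )


def pooled_stats(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray | None] | None = None,
) -> ChannelStats:
    """Statistics over the pooled pixels of several lαβ images.

    Pooling pixels (rather than averaging per-image statistics) is the
    well-defined generalization when several reference frames are given.
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    if masks is None:
        masks = [None] * len(images)
    pixels = np.concatenate([_masked_pixels(im, m) for im, m in zip(images, masks)])
    return ChannelStats(
        mean=pixels.mean(axis=0), std=pixels.std(axis=0), n_pixels=pixels.shape[0]
    )


def auto_border_mask(rgb: np.ndarray, threshold: float = AUTO_BORDER_THRESHOLD) -> np.ndarray:
    """Boolean mask excluding near-black pixels (circular FOV border fill).

    A pixel participates when its BT.601 luminance is at least
    ``threshold`` (default 10/255 in unit range).
    """
    arr = np.asarray(rgb, dtype=np.float64)
    luminance = arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114
    return luminance >= threshold


def transfer_statistics(
    src: np.ndarray, src_stats: ChannelStats, tgt_stats: ChannelStats
) -> np.ndarray:
    """Impose target per-axis moments on a source lαβ image.

    Each axis is remapped affinely: subtract the source mean, scale by
    the ratio of target to source standard deviation, add the target
    mean. An axis whose source std is zero carries no information to
    rescale; every pixel on that axis maps to the target mean (logged).
    """
    arr = np.asarray(src, dtype=np.float64)
    out = np.empty_like(arr)
    for axis in range(3):
        s_mean, s_std = src_stats.mean[axis], src_stats.std[axis]
        t_mean, t_std = tgt_stats.mean[axis], tgt_stats.std[axis]
        if s_std == 0.0:
            logger.warning(
                "source axis %d has zero std; mapping axis to target mean", axis
            )
            out[..., axis] = t_mean
        else:
            out[..., axis] = (arr[..., axis] - s_mean) * (t_std / s_std) + t_mean
    return out


Reference = Union[np.ndarray, Sequence[np.ndarray], ChannelStats]


@dataclass(frozen=True)
class NbiSimulation:
    """Result bundle from :func:`simulate_nbi`.

    ``simulated`` is the unit-range RGB output; ``source`` the input
    frame (kept so metric evaluation has the pair at hand);
    ``clipped_fraction`` the fraction of pixels clipped to gamut on the
    way back to RGB.
    """

    simulated: np.ndarray
    source: np.ndarray
    clipped_fraction: float
    source_stats: ChannelStats
    target_stats: ChannelStats


def _resolve_reference_stats(
    reference: Reference,
    mask: np.ndarray | None,
    log_floor: float,
) -> ChannelStats:
    if isinstance(reference, ChannelStats):
        return reference
    if isinstance(reference, np.ndarray):
        return compute_stats(colorspace.rgb_to_lab(reference, floor=log_floor), mask)
    # sequence of reference frames: pool pixels
    labs = [colorspace.rgb_to_lab(np.asarray(r), floor=log_floor) for r in reference]
    return pooled_stats(labs, None if mask is None else [mask] * len(labs))


def simulate_nbi(
    src: np.ndarray,
    reference: Reference,
    mask: np.ndarray | None = None,
    log_floor: float = colorspace.DEFAULT_LOG_FLOOR,
) -> NbiSimulation:
    """Simulate an NBI frame from a WLI frame.

    Runs the full pipeline: RGB → LMS → log-LMS → lαβ, statistics
    transfer toward the reference, then the inverse chain back to a
    clipped unit-range RGB frame.

    Parameters
    ----------
    src:
        Unit-range WLI frame, shape (H, W, 3).
    reference:
        Either an NBI reference frame (statistics computed on the fly),
        a sequence of reference frames (pixels pooled), or precomputed
        :class:`ChannelStats`.
    mask:
        Optional boolean (H, W) mask restricting *statistics* to a
        region (e.g. excluding the black FOV border); the transfer
        itself is applied to every pixel.
    log_floor:
        Clamp for the LMS logarithm.
    """
    src = np.asarray(src, dtype=np.float64)
    if src.ndim != 3 or src.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) source image, got shape {src.shape}")
    if mask is not None and np.asarray(mask).shape != src.shape[:2]:
        raise ValueError("mask shape does not match source image")

    tgt_stats = _resolve_reference_stats(reference, mask, log_floor)
    src_lab = colorspace.rgb_to_lab(src, floor=log_floor)
    src_stats = compute_stats(src_lab, mask)
    out_lab = transfer_statistics(src_lab, src_stats, tgt_stats)
    simulated, clipped = colorspace.lab_to_rgb(out_lab, return_clipped_fraction=True)
    return NbiSimulation(
        simulated=simulated,
        source=src,
        clipped_fraction=clipped,
        source_stats=src_stats,
        target_stats=tgt_stats,
    )
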