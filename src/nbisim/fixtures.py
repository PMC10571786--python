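"""Deterministic synthetic endoscopy-frame generator.

Stands in for clinical data: frames follow a log-linear scene model —
a base mucosa color multiplied by a lognormal reflectance texture
(coarse illumination-scale component plus fine mucosal texture), a
radial illumination falloff (endoscope light is a point source), and an
exponential absorption term along vessel-like curvilinear strokes —
plus additive sensor noise, optional saturated elliptical specular
highlights ("flare"), optional Gaussian blur, and an optional circular
field-of-view border. Because every scene factor is an exponential of
the same underlying fields, the log-image is affine in those fields,
which makes the lαβ statistics of differently rendered views of one
scene exactly comparable.

Geometry is generated separately from rendering, so the same anatomy
can be drawn with a white-light (mucosa-pink) palette and a narrow-band
(green, darker, contrast-enhanced) palette to make matched WLI /
NBI-reference pairs. The NBI rendering deepens vessels and doubles the
log-domain texture contrast — the enhanced mucosal contrast that
narrow-band illumination exists to provide.

Randomness is pinned to numpy's PCG64 generator with explicit seed
sequences per component ([seed, 0] background fields and noise,
[seed, 1] vessels, [seed, 2] highlights), so identical specs give
bit-identical frames and changing one degradation parameter does not
perturb the shared anatomy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

#: Palette centers (unit-range RGB). Qualitative fixture constants:
#: pinkish mucosa under white light, darker green-shifted appearance
#: under narrow-band illumination.
PALETTES = {
    "mucosa_pink": np.array([0.80, 0.55, 0.52]),
    "nbi_green": np.array([0.35, 0.50, 0.42]),
}

#: Log-domain amplitude of the shared reflectance texture.
TEXTURE_AMPLITUDE = 0.10
#: Log-domain amplitude of the per-channel (chromatic) texture.
CHROMA_AMPLITUDE = 0.02
#: Correlation length (pixels) of the fine texture component.
FINE_TEXTURE_SIGMA = 3.0
#: Weight of the fine component relative to the coarse one.
FINE_TEXTURE_WEIGHT = 1.5
#: Correlation length (pixels) of the chromatic texture.
CHROMA_TEXTURE_SIGMA = 2.5
#: Radial illumination falloff at the frame corners (0 = flat field).
VIGNETTE_STRENGTH = 0.25
#: Std of additive per-pixel sensor noise (unit range), applied after
#: the optics, so blur does not remove it.
SENSOR_NOISE_STD = 0.01

#: NBI rendering of a pair: extra vessel absorption, global darkening,
#: and log-domain texture-contrast gain.
NBI_VESSEL_GAIN = 1.6
NBI_DARKEN = 0.85
NBI_TEXTURE_GAIN = 2.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters controlling fixture generation.

    ``vessel_contrast`` is the peak absorption exponent at a vessel
    centerline (darkening factor exp(−vessel_contrast));
    ``highlight_fraction`` the target fraction of saturated pixels
    (≤ 0.3); ``blur_sigma`` the Gaussian blur in pixels. Identical
    spec + seed gives bit-identical output.
    """

    width: int = 640
    height: int = 480
    base_hue: str = "mucosa_pink"
    vessel_count: int = 12
    vessel_contrast: float = 0.35
    highlight_fraction: float = 0.0
    blur_sigma: float = 0.0
    fov_mask: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError("frame must have positive area")
        if self.base_hue not in PALETTES:
            raise ValueError(f"unknown base_hue {self.base_hue!r}")
        if not 0.0 <= self.vessel_contrast <= 1.0:
            raise ValueError("vessel_contrast must lie in [0, 1]")
        if not 0.0 <= self.highlight_fraction <= 0.3:
            raise ValueError("highlight_fraction must lie in [0, 0.3]")
        if self.blur_sigma < 0 or self.vessel_count < 0:
            raise ValueError("blur_sigma and vessel_count must be nonnegative")


@dataclass(frozen=True)
class SceneGeometry:
    """Seed-determined anatomy shared by all renderings of a spec."""

    shared_texture: np.ndarray  # (H, W), zero mean, unit std
    chroma_texture: np.ndarray  # (H, W, 3), per-channel, unit std
    sensor_noise: np.ndarray  # (H, W, 3), standard normal
    vessel_profile: np.ndarray  # (H, W) in [0, 1], Gaussian cross-section
    highlight_mask: np.ndarray  # (H, W) boolean
    fov_mask: np.ndarray | None  # (H, W) boolean, True inside the FOV


def _normalized(field: np.ndarray) -> np.ndarray:
    std = field.std()
    return (field - field.mean()) / std if std > 0 else field - field.mean()


def _background_fields(spec: SyntheticSpec):
    # coarse illumination-scale component plus fine mucosal texture; the
    # fine scale is what motion blur visibly destroys
    rng = np.random.default_rng([spec.seed, 0])
    shape = (spec.height, spec.width)
    coarse = gaussian_filter(
        rng.standard_normal(shape), sigma=min(spec.height, spec.width) / 10.0
    )
    fine = gaussian_filter(rng.standard_normal(shape), sigma=FINE_TEXTURE_SIGMA)
    shared = _normalized(
        _normalized(coarse) + FINE_TEXTURE_WEIGHT * _normalized(fine)
    )
    chroma = np.stack(
        [
            _normalized(
                gaussian_filter(rng.standard_normal(shape), sigma=CHROMA_TEXTURE_SIGMA)
            )
            for _ in range(3)
        ],
        axis=-1,
    )
    noise = rng.standard_normal((spec.height, spec.width, 3))
    return shared, chroma, noise


def _vessel_profile(spec: SyntheticSpec) -> np.ndarray:
    rng = np.random.default_rng([spec.seed, 1])
    canvas = np.zeros((spec.height, spec.width))
    for _ in range(spec.vessel_count):
        y = rng.uniform(0, spec.height)
        x = rng.uniform(0, spec.width)
        angle = rng.uniform(0, 2 * np.pi)
        n_steps = int(rng.uniform(0.3, 0.7) * min(spec.height, spec.width))
        # random-walk polyline: unit steps with direction jitter
        jitter = rng.normal(0.0, 0.08, size=n_steps)
        for k in range(n_steps):
            angle += jitter[k]
            y += np.sin(angle)
            x += np.cos(angle)
            iy, ix = int(round(y)), int(round(x))
            if 0 <= iy < spec.height and 0 <= ix < spec.width:
                canvas[iy, ix] = 1.0
    profile = gaussian_filter(canvas, sigma=1.4)
    peak = profile.max()
    if peak > 0:
        profile /= peak
    return profile


def _highlight_mask(spec: SyntheticSpec, fov: np.ndarray | None) -> np.ndarray:
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    if spec.highlight_fraction <= 0:
        return mask
    rng = np.random.default_rng([spec.seed, 2])
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    denom = float(fov.sum()) if fov is not None else float(mask.size)
    scale = min(spec.height, spec.width)
    # accrete small ellipses until the union reaches the target coverage;
    # each ellipse covers <~0.2% of the frame, so overshoot stays well
    # inside the ±20% relative tolerance on the saturated fraction
    for _ in range(100_000):
        covered = (mask & fov).sum() / denom if fov is not None else mask.mean()
        if covered >= spec.highlight_fraction:
            break
        cy = rng.uniform(0.1, 0.9) * spec.height
        cx = rng.uniform(0.1, 0.9) * spec.width
        a = rng.uniform(0.008, 0.025) * scale
        b = rng.uniform(0.008, 0.025) * scale
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def _fov_circle(spec: SyntheticSpec) -> np.ndarray:
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    cy, cx = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0
    radius = min(spec.height, spec.width) / 2.0
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def scene_geometry(spec: SyntheticSpec) -> SceneGeometry:
    """Generate the seed-determined anatomy for a spec."""
    shared, chroma, noise = _background_fields(spec)
    fov = _fov_circle(spec) if spec.fov_mask else None
    return SceneGeometry(
        shared_texture=shared,
        chroma_texture=chroma,
        sensor_noise=noise,
        vessel_profile=_vessel_profile(spec),
        highlight_mask=_highlight_mask(spec, fov),
        fov_mask=fov,
    )


def render_frame(
    geometry: SceneGeometry,
    spec: SyntheticSpec,
    palette: str | None = None,
    darken: float = 1.0,
    vessel_gain: float = 1.0,
    texture_gain: float = 1.0,
) -> np.ndarray:
    """Render one geometry with a palette into a unit-range RGB frame.

    The scene model is multiplicative (log-linear):

        image = base · exp(texture) · shading · exp(−absorption) · darken

    then Gaussian blur (optics), additive sensor noise, saturated
    highlights (specular flare stays sharp — it is re-imposed after the
    blur), and the circular FOV border.
    """
    base = PALETTES[palette or spec.base_hue]
    log_texture = texture_gain * (
        TEXTURE_AMPLITUDE * geometry.shared_texture[..., None]
        + CHROMA_AMPLITUDE * geometry.chroma_texture
    )
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    cy, cx = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (cy**2 + cx**2)
    shading = 1.0 - VIGNETTE_STRENGTH * r2
    absorption = (
        spec.vessel_contrast * vessel_gain * geometry.vessel_profile[..., None]
    )
    img = base * np.exp(log_texture - absorption) * shading[..., None] * darken
    img = np.clip(img, 0.0, 1.0)
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
    img = img + SENSOR_NOISE_STD * geometry.sensor_noise
    img[geometry.highlight_mask] = 1.0
    if geometry.fov_mask is not None:
        img[~geometry.fov_mask] = 0.0
    return np.clip(img, 0.0, 1.0)


def generate_frame(spec: SyntheticSpec) -> np.ndarray:
    """Generate one synthetic frame (unit-range RGB, H×W×3)."""
    return render_frame(scene_geometry(spec), spec)


def generate_pair(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the same anatomy as a (WLI, NBI-reference) pair.

    The WLI frame uses the mucosa-pink palette; the NBI reference uses
    the green palette, is globally darker, renders vessels at higher
    contrast and the mucosal texture at double log-domain contrast —
    the hallmark vessel and texture enhancement of narrow-band light.
    """
    geometry = scene_geometry(spec)
    wli = render_frame(geometry, spec, palette="mucosa_pink")
    nbi = render_frame(
        geometry,
        spec,
        palette="nbi_green",
        darken=NBI_DARKEN,
        vessel_gain=NBI_VESSEL_GAIN,
        texture_gain=NBI_TEXTURE_GAIN,
    )
    return wli, nbi


def degradation_series(
    spec: SyntheticSpec, kind: str, levels: int
) -> list[np.ndarray]:
    """Frames with identical anatomy and increasing degradation.

    ``kind`` is ``"blur"`` (blur_sigma = 0, 1, 2, … pixels) or
    ``"highlight"`` (saturated fraction = 0, 0.05, 0.10, …, capped at
    0.3). Level 0 is the undegraded frame.
    """
    if levels < 2:
        raise ValueError("levels must be at least 2")
    frames = []
    for k in range(levels):
        if kind == "blur":
            level_spec = dataclasses.replace(spec, blur_sigma=float(k))
        elif kind == "highlight":
            level_spec = dataclasses.replace(
                spec, highlight_fraction=min(0.3, 0.05 * k)
            )
        else:
            raise ValueError(f"unknown degradation kind {kind!r}")
        frames.append(generate_frame(level_spec))
    return frames
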