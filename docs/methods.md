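# Methods

## Model

`nbisim` treats NBI simulation as global color-statistics transfer.
A WLI frame and an NBI reference are mapped into Ruderman's lαβ space —
the RGB→LMS cone-response matrix, a base-10 logarithm, then the
orthogonal opponent decorrelation diag(1/√3, 1/√6, 1/√2) ·
[[1,1,1],[1,1,−2],[1,−1,0]]. Because the axes of lαβ are close to
statistically independent for natural scenes, the color character of
the reference is carried over by matching the first two moments per
axis independently:

    out_axis = (x_axis − μ_src) · (σ_ref / σ_src) + μ_ref

followed by the inverse chain (inverse decorrelation = matrix
transpose, base-10 exponentiation, inverse cone matrix, clip to gamut).

Assumptions worth stating explicitly:

- **Global statistics suffice.** The map is a per-axis affine recolor;
  it cannot move content around, so it works when source and reference
  are compositionally similar (two mucosa frames) and fails when they
  are not. Region-wise or content-aware transfer is out of scope.
- **Linear RGB.** Inputs are treated as linear after division by 255;
  no sRGB de-gamma is applied. This matches the convention of the
  transfer method itself but means a camera's gamma is absorbed into
  the statistics. Documented limitation.
- **No illumination physics.** The method imitates the *appearance* of
  NBI; it does not model the narrow-band illumination spectrum or
  hemoglobin absorption. A simulated frame is a recolored WLI frame,
  nothing more.

## Numerical choices

- **Log floor.** log₁₀ is undefined at 0 and endoscopy frames contain
  black borders, so LMS values are clamped to a floor (default 1/255,
  one byte step) before the logarithm. Frames whose LMS values exceed
  the floor round-trip through the full chain to < 1e−6.
- **Population standard deviation (1/N).** Makes moment imposition and
  idempotence exact identities rather than approximate ones; at
  640×480 the difference from 1/(N−1) is ~1.6 × 10⁻⁶ relative.
- **Degenerate axes.** A source axis with zero variance carries no
  signal to rescale; it maps to the reference mean (logged), never a
  division error.
- **Inverse decorrelation by transpose.** The scaled decorrelation
  matrix is orthogonal, so its inverse is exact; the cone matrix is
  inverted numerically once at import.
- **Gamut handling.** The inverse chain clips to [0,1]; log-LMS values
  are clamped to ±12 decades before exponentiation so absurd inputs
  saturate instead of overflowing to NaN. The clipped-pixel fraction is
  logged and reported per frame.
- **Quantization.** All computation is in unit-range float64; byte
  conversion happens once at the I/O boundary, rounding half-up, so a
  write/read round trip is byte-exact.
- **Masking.** Statistics can optionally exclude near-black pixels
  (luminance < 10/255, the capsule's circular field-of-view fill). The
  transfer itself always applies to every pixel. Default is
  whole-frame, which is the faithful reading of the equations.
- **Pooled references.** Several reference frames are summarized by
  pooling their pixels, not by averaging per-frame statistics — the
  former is the statistics of a well-defined pixel population.

## Metrics

- **SSIM**: BT.601 grayscale luminance, Gaussian window σ = 1.5 (11×11
  support), K1 = 0.01, K2 = 0.03, dynamic range 255,
  population-weighted covariances — the standard configuration.
  Computed by scikit-image; the test suite checks it against an
  independent double-loop sliding-window implementation to 1e−10.
  Reported as a percentage in user-facing output, stored in [−1, 1].
- **PSNR**: 10·log₁₀(255²/MSE) over all three channels; identical
  frames report the `inf` sentinel (written literally in CSV).
- **Entropy**: Shannon entropy of the 256-bin grayscale histogram, in
  bits (0·log 0 := 0), the common texture-entropy convention. The CSV
  reports both the absolute difference in bits and the difference
  relative to the WLI entropy in percent, since both conventions exist
  in the literature.

## Synthetic frame generator

The generator emulates capsule-endoscopy frames for testing and
benchmarking, not clinical realism. It is a log-linear scene model:

    frame = base ⊙ exp(texture) ⊙ shading ⊙ exp(−absorption) · darken

- **Palettes**: mucosa pink (0.80, 0.55, 0.52) for WLI; darker green
  (0.35, 0.50, 0.42) for the NBI look. Fixture constants, not claims
  about real tissue.
- **Texture**: a shared lognormal reflectance field (coarse
  illumination-scale component at σ = min(H,W)/10 plus fine mucosal
  texture at σ = 3 px, weight 1.5, overall log-amplitude 0.10) and a
  small per-channel chromatic field (σ = 2.5 px, amplitude 0.02).
- **Vignette**: radial illumination falloff of 0.25 at the corners —
  endoscope light is a point source.
- **Vessels**: random-walk polylines with a Gaussian cross-section
  (σ = 1.4 px), rendered as exponential absorption with centerline
  exponent `vessel_contrast` (default 0.35, 12 vessels).
- **Sensor noise**: additive, std 0.01, applied after the blur because
  noise originates at the sensor, not in the optics. This matters: a
  blurred frame keeps its noise while losing scene texture.
- **Degradations**: saturated elliptical specular highlights accreted
  until a target area fraction is covered (each ellipse < ~0.2 % of the
  frame, so coverage lands within a few percent of the target), and
  Gaussian blur of the optics.
- **NBI rendering of a pair**: same anatomy, green palette, global
  darkening 0.85, vessel absorption ×1.6, and log-domain texture
  contrast ×2. The contrast boost is the defining feature of
  narrow-band illumination — the hemoglobin-absorption bands deepen
  both vascular and mucosal pattern contrast — and it is also what
  makes degraded frames convert visibly worse: the simulated frame
  inherits reference-scale contrast, so the more a degraded source has
  lost (blur) or corrupted (flare) its own statistics, the further the
  amplified output departs from it, and SSIM falls monotonically with
  degradation level.
- **Determinism**: numpy PCG64 with explicit seed sequences per
  component ([seed, 0] fields and noise, [seed, 1] vessels, [seed, 2]
  highlights), so one spec + seed is bit-reproducible and changing a
  degradation knob leaves the shared anatomy untouched.

What the generator does **not** emulate: lesions or any pathology,
peristaltic motion, fluid/bubbles, real vascular branching topology,
camera gamma and compression artifacts, and the actual NBI spectrum.
Tests passing on these fixtures therefore demonstrate the pipeline's
mathematical contracts (invertibility, exact moment imposition, metric
correctness, the direction of quality trends) — they do not certify
clinical image quality.

## Problem sizes

The batch evaluation protocol uses 50 synthetic 640×480 frames against
one NBI reference — the frame size and batch size of a typical
small-scale evaluation. Property checks (round trip, imposition, SSIM
oracle equivalence) use 100 random frames at 32×32 / 16×16 and 20 pairs
at 64×64; these properties are resolution-independent, so small frames
test them exactly.

## Known limitations

- A single global affine recolor cannot reproduce spatially varying NBI
  effects (e.g. depth-dependent vessel enhancement).
- Statistics from a poorly matched reference (different organ,
  lighting, or composition) produce plausible-looking but meaningless
  output; the method has no failure detector beyond the clipped-pixel
  fraction.
- PSNR between a WLI frame and its simulated NBI mostly measures the
  size of the intended color change, not conversion quality; it is
  reported because the three-metric protocol calls for it, and should
  be read comparatively across frames, not as an absolute quality
  score.
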