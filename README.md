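# nbisim

Simulated narrow-band imaging (NBI) for white-light endoscopy frames.

Video capsule endoscopes image the gastrointestinal tract with white
light only (WLI): they have no room for the narrow-band illumination
hardware (~415/540 nm, at the hemoglobin absorption peaks) that darkens
blood vessels and enhances mucosal contrast, and that makes NBI so much
better for spotting early neoplastic change. `nbisim` produces an
NBI-look frame from a WLI frame in post-processing, for researchers
building screening or computer-aided-detection pipelines on capsule
video, and evaluates how faithfully the conversion preserves the frame.

## Method

The conversion is per-axis statistics transfer in Ruderman's
decorrelated lαβ color space. Each frame is mapped

```
RGB → LMS → log₁₀ LMS → lαβ
```

with the cone-response matrix

```
⎡L⎤   ⎡0.3811 0.5783 0.0402⎤ ⎡R⎤
⎢M⎥ = ⎢0.1967 0.7244 0.0782⎥ ⎢G⎥
⎣S⎦   ⎣0.0241 0.1288 0.8444⎦ ⎣B⎦
```

and the orthogonal decorrelation l=(L̂+M̂+Ŝ)/√3, α=(L̂+M̂−2Ŝ)/√6,
β=(L̂−M̂)/√2 of the log cone responses. In lαβ the axes are nearly
independent, so matching first and second moments per axis suffices to
carry a color character across images: for each axis,

```
out = (x − μ_src) · (σ_ref / σ_src) + μ_ref
```

imposes the reference NBI frame's mean and standard deviation on the
WLI frame, after which the inverse chain returns a displayable RGB
frame. The reference can be an NBI image, several pooled images, or a
six-number JSON statistics file.

Each WLI/simulated-NBI pair is scored with the standard three-metric
protocol: SSIM (Gaussian-windowed, Wang et al. constants), PSNR on the
8-bit scale, and Shannon histogram entropy with the absolute entropy
difference.

A deterministic synthetic endoscopy-frame generator
(`nbisim.fixtures`) stands in for clinical data: mucosa-colored frames
with vessel-like curvilinear structures, radial illumination falloff,
specular highlights, blur, and sensor noise, rendered from a shared
anatomy in a WLI palette and a darker, contrast-enhanced NBI palette.

## Worked example

```
$ python examples/simulate_nbi_frame.py
frame: 640x480, seed 42
clipped fraction:      0.0000
SSIM:                  88.34 %
PSNR:                  10.90 dB
entropy (WLI):         6.106 bits
entropy (simulated):   6.248 bits
entropy difference:    0.143 bits (2.34 % of WLI)
max stats mismatch:    2.18e-14
```

SSIM near 90% says the conversion recolored the frame while keeping its
structure; the small entropy difference says the texture information
content barely changed; the low PSNR simply reflects that the intended
color change is global and large. The last line verifies the defining
property of the method: the output's lαβ statistics equal the
reference's to machine precision.

`examples/degradation_trend.py` shows the quality dependence — SSIM
between a frame and its simulated NBI falls monotonically as the source
is blurred or increasingly covered by specular flare:

```
blur series (level 0 = clean frame):      88.40 → 87.24 %
highlight series (level 0 = clean frame): 88.40 → 71.72 %
```

The same pipeline is available from the shell:

```
nbisim stats reference_nbi.png --out ref_stats.json
nbisim batch frames/*.png --stats ref_stats.json -o out/ --report report.csv
```

`batch` writes one simulated frame per source plus a CSV with per-frame
SSIM/PSNR/entropy rows and a final MEAN row.

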