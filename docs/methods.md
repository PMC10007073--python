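# Methods

## The model

`csjnd` estimates, for every pixel of each YCbCr channel θ of an 8-bit
color image, the largest intensity change the human visual system (HVS)
cannot detect — a just-noticeable-difference (JND) map. The final
threshold is

    CSJND_θ(x) = CS_θ · [ LA(x) + VM_θ^S(x) − α · min(LA(x), VM_θ^S(x)) ]

with α = 0.3, built from four ingredients.

**Luminance adaptation (LA).** Visibility depends on background
luminance: thresholds are high in the dark, minimal near mid-gray, and
rise gently toward white. With l(x) the mean of a 5×5 neighbourhood,

    LA(x) = 17 (1 − √(l/127)) + 3    for l ≤ 127
    LA(x) = 3 (l − 127)/128 + 3      for l > 127

giving LA = 20 at black, 3 at mid-gray, 6 at white, continuous at 127.

**Visual masking (VM).** Three multiplicative factors:

- *Contrast masking* — a compressive transducer of the local intensity
  spread c(x) (population standard deviation over the same 5×5 window),
  CM = 0.115 · a₁ c^2.4 / (c² + a₂²) with a₁ = 16, a₂ = 26. The wording
  in the source literature says "variance", but the half-saturation
  constant a₂ = 26 is on a gray-level scale that only a deviation-scaled
  c can reach; a `contrast_stat: var` switch preserves the alternative
  reading.
- *Pattern masking* — distortion hides in orientation-diverse texture.
  The Prewitt gradient angle, folded into [0°, 180°), is quantised into
  12 bins; the pattern complexity PC(x) is the number of occupied bins
  (the L0 norm of the orientation histogram) in a 5×5 region, and
  PM = b₁ PC^b₂ / (PC² + b₃²) with b₁ = 0.8, b₂ = 2.7, b₃ = 0.1.
  Pixels with gradient magnitude ≤ 2 gray levels have no meaningful
  orientation and are excluded, so flat regions yield PC = 0 and PM = 0
  rather than one spurious bin. Bin count and region size are config
  keys (`structure.n_bins`, `structure.region_window`).
- *Edge protection* — the HVS scrutinises edges, so thresholds near
  them are pulled down: EP = λ_θ · G(x) · W(x), where G is the maximal
  absolute response of the classical four 5×5 directional kernels
  (0°/45°/90°/135°, each normalised by 1/16), W is a Canny edge map
  (σ = 1.4, hysteresis 0.1/0.3 on normalised magnitude) assigned 0.1 on
  edge pixels and 1 elsewhere, then smoothed with a 7×7 Gaussian
  (σ = 0.8) and clipped to [0.1, 1], and λ_θ = 0.117 / 0.65 / 0.45 for
  Y / Cb / Cr. Each channel uses its own plane for G and W by default
  (`structure.edge_source: luma` shares the luma edges instead).

**Saliency modulation.** Attention concentrates distortion sensitivity:
VM^S = VM · U_S with U_S = 1 − S′, where S′ is the min–max-normalised
SDSP saliency, the pixel-wise product of a log-Gabor band-pass
frequency prior (ω₀ = 0.002, σ_F = 6.2, DC response zero), a Gaussian
centre-bias location prior (σ_D = 114 px), and a warm-color prior on
min–max-normalised L\*a\*b\* chroma (σ_C = 0.25). Saliency is computed
once from the RGB image — resized so its longer side is 256, where σ_D
is calibrated, then resized back — and shared by all three channels.
If the saliency product is constant (e.g. a uniform image), S′ is
defined as 0 everywhere: no region is distinguished, so masking is
unmodulated (U_S ≡ 1).

**NAMM fusion.** The nonlinear additivity model for masking discounts
the overlap between adaptation and masking with gain-reduction factor
α = 0.3; for α ∈ [0, 1) the fused threshold always lies between
max(LA, VM^S) and LA + VM^S.

**Color-sensitivity weighting.** The HVS resolves luma detail from
much farther away than chroma detail: the measured critical-distance
ratio is D_Y : D_Cb : D_Cr = 1 : 0.432 : 0.501. Treating each channel
as a perceptual sub-unit whose share of a unit area scales with D_θ²
gives sensitivity parameters S_θ = D_θ² / ΣD², published as
(0.695, 0.130, 0.175); their normalised reciprocals are the weights
CS_θ = 3·S_θ⁻¹ / Σ S⁻¹ = (0.291, 1.554, 1.155), summing to 3. The
published three-decimal triple mixes a truncation (the computed Y share
is 0.69559…) with roundings, so it is carried verbatim as
`PRINTED_S_PARAMS` and used as the default basis for the weights
(`color.cs_from: printed`); `cs_from: unrounded` propagates full
precision instead, giving (0.290, 1.557, 1.153).

**Variants.** `B` = LA + VM only; `S` adds saliency; `C` adds color
weights; `full` adds both. They obey the algebra
`C = CS ∘ B`, `full = CS ∘ S` exactly (tested as map identities).

## Noise injection and calibration

A JND model is validated by hiding noise under its thresholds:

    F̂_θ(x) = F_θ(x) + β · r(x) · JND_θ(x)

with r(x) a fair ±1 coin drawn independently per pixel *and per
channel* from a seeded generator (independence avoids correlated color
artifacts), and β a scalar noise-level controller. Fair comparison of
different models requires equal noise energy, so β is calibrated by
bisection to a target PSNR with the sign field frozen: clipping to
[0, 255] is applied inside the loop, so the achieved PSNR honours the
target even where thresholds exceed the available headroom. PSNR pools
the MSE over all three YCbCr planes by default (the injection perturbs
all three; `noise.psnr_domain` offers `y_only` and `rgb_pooled`).
Calibration converges to ±0.05 dB, raises a diagnostic error with the
bracket if 60 bisection steps do not suffice, and rejects identically
zero maps. The whole pipeline (maps + calibration) is bit-reproducible
given (image, config, seed).

Reported metrics: pooled PSNR, single-scale SSIM on the luma plane
(Gaussian 11×11 window, σ = 1.5, population covariances, 8-bit dynamic
range), and per-channel MSE. Learned perceptual metrics are outside
the package's scope.

## Synthetic stimuli

The fixture generator produces seven deterministic families — flat
fields, luminance ramps, sinusoidal gratings, checkerboards, step
edges, seeded i.i.d. color textures, and two-region (flat + textured)
images — each with a closed-form expectation for at least one stage:
a flat field has c = 0 and PC = 0 everywhere, so its threshold is
exactly CS_θ · LA; a grating at angle 0 occupies orientation bin 0; a
step edge has a known Canny line; the two-region image separates
saliency and allocation behaviour spatially. The canonical regression
suite holds 12 stimuli at 128×128 and 128×192 — sizes chosen so the
full pipeline runs in well under a second per image while every window
in the model (5×5 statistics, 5×5 kernels, 7×7 smoothing, Canny
support) is exercised.

What the stimuli do *not* emulate: natural-image statistics (1/f
spectra, object structure, photographic noise), so passing tests
demonstrate correctness of the computation and its invariants, not
perceptual performance on photographs; the latter requires the
original test images and human viewers or a learned quality metric.

## Numerical choices

- Borders: edge-replicate padding for every window (no artificial
  contrast at image borders).
- Degenerate min–max normalisations (constant saliency, constant
  chroma) are defined as 0, which makes U_S ≡ 1 and S_C ≡ 0 — neutral
  behaviour rather than division noise.
- `local_contrast` clips the E[x²] − E[x]² difference at 0 before the
  square root to absorb float cancellation on constant patches.
- Orientation folding uses `mod 180`, so φ and φ + 180° share a bin;
  the bin of an exactly-flat pixel is a sentinel (−1), never bin 0.
- Quantisation to 8-bit at image write time rounds half away from
  zero and clips.
- RGB↔YCbCr is full-range BT.601; the float round trip is exact to
  ~1e-13, and within 1 gray level after write-time quantisation for
  non-clipping inputs.

## Known limitations

- The model is spatial-only: no temporal masking, no foveation.
- Chroma planes reuse the luma-adaptation curve (`la_source: luma`),
  consistent with the adaptation literature the model builds on; a
  `per_channel` override exists but is untested psychophysically.
- SDSP parameters are taken from the cited detector's defaults; the
  original work does not restate them, so other choices are plausible.
- Thresholds on dense random texture grow very large in the chroma
  planes (the multiplicative masking estimate compounds); calibration
  keeps injections comparable regardless.
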