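# Methods

This note documents the models implemented in `ctiq`, the defaults chosen
where the underlying procedures are open to interpretation, and what the
synthetic study can and cannot show about real scanner data.

## Synthetic phantom sections

The generator produces functional stand-ins for the three sections of a
CIRS-610-style quality-assurance phantom on a 512×512 grid (positions scale
with image size):

* **linearity** — five circular inserts (radius 71 px) on a 150-px ring
  inside a 230-px body disk.  The real phantom's insert materials are not
  published, so the default HU values {−200, −100, 0, 120, 990} are
  documented placeholders spanning lung-like to bone-like attenuation; they
  are fully config-exposed.
* **high-resolution** — five 56×56 px bar groups with bar widths 8, 6, 4, 3
  and 2 px at +400 HU contrast, i.e. spatial frequencies increasing from
  0.0625 to 0.25 cycles/px.
* **artifact** — two high-HU (990) inserts, radius 40 px, left and right of
  centre.  Only the high-contrast *geometry* is reproduced; streak physics,
  beam hardening and sinogram-domain effects are out of scope.

The body disk defaults to 50 HU rather than water-equivalent 0 HU so that
ROI means — and therefore SNR — are well defined on every section; air is
−1000 HU.  Geometry is rendered at 4× resolution and area-averaged
(anti-aliasing that keeps ROI means independent of grid phase), then blurred
with a Gaussian of 2 px FWHM to model finite system resolution.  Rendering
is deterministic; the seed parameter only enters the provenance label.

**Reconstruction surrogates.** The commercial deep-learning reconstruction
engines compared in phantom studies have no published equations, so the
pipeline applies clearly-labelled surrogates instead: Gaussian blurs of SD
2.0 / 1.5 / 1.25 / 1.0 px ("surrogate-H", "-smoother", "-M", "-standard")
and a sharpening preset (0.5 px blur + unsharp mask, gain 0.8,
"surrogate-sharper").  These produce a strict smooth-to-sharp ordering used
to validate pipeline plumbing — they are *not* models of any vendor
algorithm, and results obtained with them say nothing about commercial
reconstruction performance.

## Poisson–Gaussian noise model

Injection follows `y = p + η(p)δ` with `η²(p) = αp + σ²` and Gaussian `δ`
(the defining property of `δ` is zero mean and unit SD; a distribution must
be chosen, and Gaussian is the natural limit for compounded quantum and
electronic noise).  Because HU are signed while the Poisson term requires a
nonnegative signal, injection and estimation shift intensities by a
configurable `offset_hu` (default +1024, placing air at ≈ 24); the offset is
removed before images are returned, and estimated `α` values refer to the
shifted frame with the offset recorded in the diagnostics.  If
`αp + σ² < 0` anywhere the injector aborts and names the offset that would
fix it.

Named parameter presets `overweight` (α = 0.15, σ = 3.15 HU) and `obese`
(α = 0.31, σ = 4.16 HU) correspond to the BMI-stratified noise levels
reported for patient images; the noise frame in which such values are
measured is not standardised, so the recovery experiments inject and
estimate in the same shifted-HU frame, which is self-consistent.

Replicates differ only by noise seed; one master seed deterministically
spawns per-replicate child seeds (`numpy.random.SeedSequence`).

## Patch-based (α, σ) estimation

Estimation tiles the image into non-overlapping 16×16 patches, drops every
patch within one patch of the phantom/air boundary (air = pixels ≤ −900 HU;
the exclusion band is the boundary dilated by one patch on both sides), and
computes for each remaining patch its mean `m` (shifted frame) and its
plane-detrended variance `v` (residual variance about the patch's best-fit
plane, unbiased with dof = 256 − 3), so smooth intensity gradients are not
mistaken for noise.  Patches deep inside air are deliberately *kept*: the
variance–mean law holds there too, and the low-signal level (m ≈ 24) is
what anchors the Gaussian intercept — without it σ² must be extrapolated
from signal levels several hundred HU away and its estimate becomes
unusably noisy.

A patch's sample variance measures structure *plus* noise, which makes
homogeneous-patch selection delicate in two ways:

1. keeping the globally quietest patches discards whole signal levels
   (high-HU inserts have the largest noise variance under the law) and
   conditions the retained variances on being small, biasing both
   parameters low;
2. the homogeneity score and the fitted variance share the same noise
   realisation, so any quantile cut on the score is a cut on the fit data.

The estimator therefore proceeds in two stages.  First, patches are binned
by mean (up to 8 quantile bins) and within each bin the lowest-variance
`homogeneity_quantile` fraction (default 0.25) is kept — a level-balanced
initial selection that is robust to structured outliers.  Second, the
variance–mean line fitted to that selection is used to screen *all* patches:
a patch is kept iff its variance lies below the fitted expectation plus 3.5
chi-square SDs (relative SD √(2/253) for a flat patch), and the fit/screen
cycle repeats until stable.  Structured patches inflate their variance far
above this band and are trimmed; flat patches are retained regardless of
their noise realisation (the one-sided 3.5σ cut excises < 0.1 % of them), so
the final fit is essentially free of selection bias at every signal level.

The final regression is weighted least squares with weights `1/fitted²`
(the correct covariance model for chi-square-distributed patch variances),
iterated twice, with slope and intercept clipped at zero.  `α_sd` comes
from the WLS coefficient covariance and `σ_sd` from the delta method
(`σ_sd = σ²_sd / 2σ`).  Degenerate regimes are handled explicitly: exact
on-line data reproduce the line to machine precision; patch means spanning
≤ 1 HU make the slope unidentifiable, and a σ-only estimate is returned
with `alpha_reliable = False` and a warning.  A pair-based mode computes
patch variances on the noisy−clean difference image when a matching clean
image is available, removing structure leakage entirely.

The public `select_homogeneous_patches` operation keeps the simpler
single-pass semantics (rank by plane-detrended variance normalised by
shifted mean, keep the lowest-scoring fraction, raster-order ties) — useful
for inspection and masking — while `estimate_noise_params` uses the
two-stage scheme above.

## Metrics

All nine metrics operate on `ImageGrid` arrays in HU.  Conventions:

* **SNR** uses the mean of the signal ROI and the SD of the background ROI.
  On the linearity section the signal ROI coincides with the
  highest-contrast insert; other sections use a body-centre signal ROI.
* **PSNR** uses `L` = the reference's dynamic range by default ("maximum
  brightness" is ambiguous for signed HU; a fixed 4096 can be configured).
  Identical images return an explicit `+inf` sentinel flagged
  `identical_images` rather than a numeric overflow.
* **nRMSE** divides by the reference's max − min.
* **CNR** uses the absolute mean difference so material ordering cannot
  flip signs, over the root-sum of within-ROI variances; one value per
  lesion ROI (five on the linearity section).
* **SSIM** is computed in the global-statistic form (whole-image means,
  variances, covariance) with k₁ = 0.01, k₂ = 0.03 — the conventional
  stabilising constants.  A non-overlapping sliding-window mean-SSIM is
  available behind a flag but is not the default, since the global form is
  the one the evaluation is defined with.
* **UQI** is the constant-free luminance × structure product; undefined (an
  error) when both images are constant.
* **GMSD** uses Prewitt masks scaled by 1/3 (matching the metric's original
  formulation) and ε = 0.0026 L², scaled to the working intensity range;
  the population SD of the similarity map is returned.  Two constant images
  give 0 (the ε guard makes the similarity map identically 1).
* **GM** first normalises the image to [0, 1] by its own range and uses
  Sobel masks scaled to unit absolute sum, making the score invariant to
  affine intensity rescaling; a flat image scores 0 by convention.
* **FSIM** combines phase congruency (primary feature) and gradient
  magnitude (auxiliary; Sobel on range-normalised images) with
  ε₁ = 10⁻⁴ on the PC scale and ε₂ = 10⁻³ on the normalised-gradient
  scale, pooled with max(PC₁, PC₂) weights.  Two featureless images raise
  an error (zero pooling weight).

**Phase congruency** uses 4 log-Gabor scales (smallest wavelength 6 px,
octave multiplier 2, σ_onf = 0.55) × 4 orientations, a Butterworth lowpass
against wrap-around ringing, and reflect padding (32 px) before the FFT so
the periodic extension does not fabricate border edges.  The per-orientation
noise threshold is the Rayleigh-derived mean-plus-2-SD of the energy
expected from the smallest-scale response median.  Numerator, denominator
and threshold all scale linearly with contrast, so the PC map is invariant
to affine intensity rescaling; values are clipped to [0, 1].

All convolutions use reflect boundary handling, which avoids spurious
phantom-edge gradients.

## Evaluation pipeline

For each module × replicate × preset: the clean phantom is rendered once per
module, noise is injected with the replicate's child seed, the surrogate is
applied, and all metrics are computed — full-reference metrics against the
clean phantom (the stand-in for a reconstruction baseline), SNR/CNR from the
default ROI layout.  The default layout places one 100×100 ROI centred on
each linearity insert (shrunk to the circle's inscribed square with a
warning when the insert is too small), a background ROI at the disk centre,
and for the other sections a centre signal ROI plus a background ROI 114
scaled-px below centre, all in uniform body material.  Three replicates are
the default; averages are exact arithmetic means over replicates, and
reports carry the config hash, master seed and constants for replay.

## What the synthetic study does and does not show

Passing tests demonstrate that the metric implementations are correct
(against independent naive oracles and closed forms), that the noise model
and its estimator are mutually consistent at realistic parameter settings,
and that the pipeline is deterministic and orders smoothing/sharpening
operators as expected.  The synthetic phantoms contain no anatomical
texture, motion, beam hardening or spatially correlated
(reconstruction-kernel-coloured) noise, and the surrogates are not vendor
algorithms — so absolute metric values here are not comparable to values
measured on physical phantom scans reconstructed by commercial engines, and
no claim about those engines can be derived from this package.

## Problem sizes

Default experiments run at the phantom's native 512×512; the test suite
exercises the same code paths at 128–1024 px where a smaller grid suffices
to establish the property under test, keeping the full suite under half a
minute on one CPU.  The acceptance script's recovery experiment uses the
full 512×512 phantom and 20 replicates.
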