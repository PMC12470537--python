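# ctiq — quantitative low-dose CT image-quality evaluation

`ctiq` is a desk-scale, fully synthetic re-implementation of the quantitative
image-quality evaluation used in low-dose CT reconstruction studies.  It is
aimed at medical-physics and image-processing researchers who want a tested,
reproducible pipeline for comparing denoising/reconstruction operators on
phantom-style images without access to a scanner: synthetic stand-ins for the
three AAPM CIRS-610 phantom sections are degraded with a signal-dependent
Poisson–Gaussian noise model, processed by parameterised
reconstruction-strength surrogates, and scored with nine quantitative metrics
grouped into three evaluation categories, with replicate averaging and
tabular reports.

## The models

**Noise.** Low-dose degradation follows the mixed Poisson–Gaussian model

```
y(x) = p(x) + η(p(x)) δ(x),        η²(p) = α p + σ²
```

where `p` is the ideal image (shifted to a nonnegative frame, +1024 HU by
default), `δ` is zero-mean unit-SD noise, `α` scales the signal-dependent
quantum component and `σ` (HU) is the SD of the electronic component.  Named
parameter pairs measured from BMI-stratified patient images are built in
(`overweight`: α ≈ 0.15, σ ≈ 3.15; `obese`: α ≈ 0.31, σ ≈ 4.16).  The same
module estimates `(α, σ)` from a noisy image by tiling it into 16×16
patches, computing each patch's mean and plane-detrended variance, and
fitting the variance–mean law `v = α m + σ²` with a level-balanced,
outlier-trimmed weighted regression (see `docs/methods.md`).

**Metrics.** Three categories:

| category | metrics |
|---|---|
| noise & signal fidelity | SNR = 10 log₁₀(M²/β²), PSNR = 20 log₁₀(L/√E), nRMSE = RMSE/range, CNR = \|I_t − I_b\|/√(σ_t² + σ_b²) |
| structural similarity | SSIM (global statistics), FSIM (phase congruency + gradient), UQI |
| edge & structural distortion | GMSD (SD of the gradient-similarity map), GM (mean normalised gradient magnitude) |

Phase congruency is computed with a multi-scale, multi-orientation log-Gabor
quadrature filter bank with noise-threshold subtraction; every metric has an
independent naive-loop oracle twin in the test suite.

## Worked example

Generate the default 512×512 linearity phantom (five circular inserts of
−200, −100, 0, 120 and 990 HU in a 50-HU body disk), degrade it at the
obese-patient noise setting, and recover the noise parameters:

```python
from ctiq import (BMI_NOISE_PRESETS, default_spec, make_phantom,
                  inject_noise, estimate_noise_params)

spec = default_spec("linearity")            # 512x512, five inserts
clean = make_phantom(spec)
noisy = inject_noise(clean, BMI_NOISE_PRESETS["obese"], seed=3)
params, diag = estimate_noise_params(noisy, patch_size_px=16)
print(f"alpha = {params.alpha:.3f} +/- {params.alpha_sd:.3f}")
print(f"sigma = {params.sigma:.2f} +/- {params.sigma_sd:.2f} HU")
print(f"patches used = {diag.n_patches_used}, R^2 = {diag.regression_r2:.3f}")
```

prints

```
alpha = 0.312 +/- 0.001
sigma = 4.15 +/- 0.02 HU
patches used = 687, R^2 = 0.974
```

i.e. the injected α = 0.31 and σ = 4.16 HU are recovered from a single noisy
image within the regression's quoted uncertainty (687 homogeneous 16×16
patches entered the variance–mean fit, which explains 97 % of the
patch-variance spread).

The same stages are scriptable from the shell:

```
ctiq simulate --module linearity --size 512 --seed 7 --out clean.npy
ctiq inject --bmi obese --seed 3 --in clean.npy --out noisy.npy
ctiq estimate --patch 16 --in noisy.npy
ctiq evaluate --config study.yaml --out results/
```

`ctiq evaluate` runs the full study design — for every phantom module and
noise replicate, each reconstruction surrogate is scored with all nine
metrics against the clean phantom, replicates are averaged, and
`report.csv` / `report.json` plus one summary table per category per module
are written.

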