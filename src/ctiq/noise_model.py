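"""Poisson-Gaussian mixture noise: injection and patch-based estimation.

Low-dose CT noise is modelled as signal-dependent:

    y(x) = p(x) + eta(p(x)) * delta(x),   eta^2(p) = alpha * p + sigma^2

where ``p`` is the ideal image, ``delta`` is i.i.d. zero-mean unit-SD noise
(Gaussian here), ``alpha`` scales the Poisson (quantum) component and
``sigma`` is the SD of the signal-independent (electronic) component.

HU values are signed but the Poisson term needs ``p >= 0``, so injection and
estimation both operate in a shifted frame ``p + offset_hu`` (default +1024,
placing air at ~24); the offset is removed before returning images, and the
estimated ``alpha`` refers to the shifted frame, with the offset recorded.

Estimation tiles the image into non-overlapping patches (16x16 by default)
clear of the phantom/air boundary, computes each patch's mean and
plane-detrended variance, and fits the variance-mean law
``v = alpha * m + sigma^2``.  Because a patch's sample variance measures
*structure plus noise*, homogeneous-patch selection must not simply keep the
globally quietest patches: that both discards the high- and low-signal
levels that give the regression its leverage and conditions the retained
variances on being small, biasing the fit downward.  Instead the estimator

1. bins patches by mean and keeps the lowest-variance
   ``homogeneity_quantile`` fraction *within each bin* (a level-balanced
   initial selection),
2. fits a provisional weighted line to that selection, and
3. iteratively re-admits every patch whose variance is consistent with the
   current law and trims only upper outliers (structured patches inflate
   their variance far above the chi-square scatter of flat ones), refitting
   until the trimmed set is stable.

The one-sided trim at several chi-square SDs rejects textured patches while
conditioning the retained noise variances only negligibly, so the final
weighted fit is essentially unbiased at every signal level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats

from .errors import (
    EstimationInfeasibleError,
    IllConditionedSlopeWarning,
    NoisePreconditionError,
)
from .io_formats import ImageGrid

DEFAULT_OFFSET_HU = 1024.0
DEFAULT_PATCH_SIZE = 16
DEFAULT_HOMOGENEITY_QUANTILE = 0.25
AIR_THRESHOLD_HU = -900.0
_TRIM_SD = 3.5  # one-sided outlier trim, in chi-square SDs of a flat patch
_MAX_TRIM_ITER = 20


@dataclass
class NoiseParams:
    """The Poisson-Gaussian parameter pair (alpha, sigma), optionally with
    regression standard errors when estimated from data."""

    alpha: float
    sigma: float
    alpha_sd: Optional[float] = None
    sigma_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.sigma < 0:
            raise ValueError(f"alpha and sigma must be nonnegative, got ({self.alpha}, {self.sigma})")


#: Named parameter pairs measured from BMI-stratified patient images.
BMI_NOISE_PRESETS = {
    "overweight": NoiseParams(alpha=0.15, sigma=3.15),
    "obese": NoiseParams(alpha=0.31, sigma=4.16),
}


@dataclass
class PatchEstimateDiagnostics:
    """Bookkeeping from one patch-based estimation run."""

    patch_size_px: int
    n_patches_used: int
    homogeneity_threshold: float
    regression_r2: float
    patch_stats: list[tuple[float, float]] = field(default_factory=list)
    offset_hu: float = DEFAULT_OFFSET_HU
    alpha_reliable: bool = True


def inject_noise(
    clean: ImageGrid,
    params: NoiseParams,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    offset_hu: float = DEFAULT_OFFSET_HU,
) -> ImageGrid:
    """Degrade a clean image with signal-dependent Poisson-Gaussian noise.

    The per-pixel noise SD is ``sqrt(alpha * (p + offset_hu) + sigma^2)``;
    the returned image is back in the input's HU frame.  Reproducible given
    the same seed.
    """
    p = clean.pixels
    shifted = p + offset_hu
    var = params.alpha * shifted + params.sigma ** 2
    if np.any(var < 0):
        worst = float(np.min(shifted))
        raise NoisePreconditionError(
            f"alpha*p + sigma^2 is negative: minimum shifted signal is {worst:.1f} HU; "
            f"increase offset_hu to at least {offset_hu - worst:.1f}"
        )
    if params.alpha == 0 and params.sigma == 0:
        noisy = p.copy()
    else:
        rng = np.random.default_rng(seed)
        noisy = p + np.sqrt(var) * rng.standard_normal(p.shape)
    return clean.with_pixels(noisy, provenance=f"{clean.provenance}|noisy(a={params.alpha},s={params.sigma})")


# ---------------------------------------------------------------------------
# patch machinery


def _tile_patches(shape: tuple[int, int], patch: int) -> list[tuple[int, int]]:
    h, w = shape
    return [(r, c) for r in range(0, h - patch + 1, patch) for c in range(0, w - patch + 1, patch)]


def _patch_moments(
    image_px: np.ndarray,
    coords: Sequence[tuple[int, int]],
    patch: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Patch means and plane-detrended variances (unbiased, dof = n - 3).

    Detrending removes each patch's best-fit plane so that smooth intensity
    gradients do not masquerade as noise.
    """
    n = len(coords)
    stack = np.empty((n, patch * patch), dtype=np.float64)
    for i, (r, c) in enumerate(coords):
        stack[i] = image_px[r:r + patch, c:c + patch].ravel()

    rr, cc = np.meshgrid(np.arange(patch), np.arange(patch), indexing="ij")
    X = np.column_stack([np.ones(patch * patch), rr.ravel(), cc.ravel()]).astype(float)
    resid_maker = np.eye(patch * patch) - X @ np.linalg.pinv(X)
    resid = stack @ resid_maker.T
    dof = patch * patch - 3
    variances = np.einsum("ij,ij->i", resid, resid) / dof
    means = stack.mean(axis=1)
    return means, variances


def _air_excluded_coords(
    image_px: np.ndarray, patch: int
) -> list[tuple[int, int]]:
    """Tile coordinates whose patches stay clear of the phantom/air boundary.

    The boundary band is the set of pixels within one patch of the air edge
    on either side (air mask = pixels <= -900 HU, dilated by one patch and
    intersected with the matching dilation of non-air).  Tiles deep inside
    the body *or* deep inside air are kept: the variance-mean law holds in
    both, and low-signal air tiles are what pin down the Gaussian intercept.
    """
    coords = _tile_patches(image_px.shape, patch)
    air = image_px <= AIR_THRESHOLD_HU
    if air.any() and not air.all():
        struct = np.ones((patch, patch), dtype=bool)
        band = (ndimage.binary_dilation(air, structure=struct)
                & ndimage.binary_dilation(~air, structure=struct))
        coords = [
            (r, c) for (r, c) in coords if not band[r:r + patch, c:c + patch].any()
        ]
    return coords


def _lowest_fraction(scores: np.ndarray, quantile: float) -> tuple[np.ndarray, float]:
    """Indices of the lowest-scoring fraction (stable sort: raster-order ties)."""
    n_keep = max(1, int(math.floor(quantile * len(scores) + 1e-9)))
    order = np.argsort(scores, kind="stable")
    keep = np.sort(order[:n_keep])
    threshold = float(scores[order[n_keep - 1]])
    return keep, threshold


def select_homogeneous_patches(
    image: ImageGrid,
    patch_size_px: int = DEFAULT_PATCH_SIZE,
    homogeneity_quantile: float = DEFAULT_HOMOGENEITY_QUANTILE,
    offset_hu: float = DEFAULT_OFFSET_HU,
) -> list[tuple[int, int]]:
    """Return (row, col) origins of the most homogeneous non-overlapping patches.

    Patches straddling the phantom/air boundary (pixels <= -900 HU) are
    never returned.  The homogeneity score is the plane-detrended patch
    variance normalised by the shifted patch mean; the lowest-scoring
    ``homogeneity_quantile`` fraction is kept, ties broken in raster order.
    """
    if patch_size_px < 4:
        raise EstimationInfeasibleError(f"patch_size_px must be >= 4, got {patch_size_px}")
    if not (0 < homogeneity_quantile <= 1):
        raise EstimationInfeasibleError(
            f"homogeneity_quantile must be in (0, 1], got {homogeneity_quantile}")
    coords = _air_excluded_coords(image.pixels, patch_size_px)
    if len(coords) < 2:
        raise EstimationInfeasibleError(
            f"fewer than 2 usable {patch_size_px}x{patch_size_px} patches in a "
            f"{image.height}x{image.width} image")
    means, variances = _patch_moments(image.pixels, coords, patch_size_px)
    scores = variances / np.maximum(means + offset_hu, 1.0)
    keep, _ = _lowest_fraction(scores, homogeneity_quantile)
    return [coords[i] for i in keep]


def fit_variance_mean_line(means: np.ndarray, variances: np.ndarray,
                           weighted: bool = True, n_reweight: int = 2):
    """Least-squares fit of ``v = alpha * m + sigma^2`` with nonnegativity
    clipping; returns (alpha, sigma2, alpha_sd, sigma2_sd, r2).

    Patch variances are approximately chi-square distributed with SD
    proportional to their own expectation, so after an initial ordinary fit
    the line is refit with weights ``1 / fitted^2`` (iterated
    ``n_reweight`` times).  ``weighted=False`` gives the plain OLS fit; in
    either mode, exact on-line (m, v) pairs are recovered to machine
    precision, which is how the routine is oracle-tested.
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if np.ptp(variances) == 0 or np.ptp(means) == 0:
        # degenerate: flat response; slope 0, intercept = mean level
        intercept = float(np.mean(variances))
        return 0.0, max(intercept, 0.0), 0.0, 0.0, 1.0 if np.ptp(variances) == 0 else 0.0
    res = stats.linregress(means, variances)
    slope, intercept = float(res.slope), float(res.intercept)
    slope_sd, intercept_sd = float(res.stderr), float(res.intercept_stderr)
    r2 = float(res.rvalue ** 2)
    if weighted:
        X = np.column_stack([means, np.ones_like(means)])
        for _ in range(n_reweight):
            fitted = slope * means + intercept
            floor = max(float(np.median(np.abs(fitted))), 1e-12)
            w = 1.0 / np.maximum(fitted, 0.1 * floor) ** 2
            XtWX = X.T @ (w[:, None] * X)
            beta = np.linalg.solve(XtWX, X.T @ (w * variances))
            slope, intercept = float(beta[0]), float(beta[1])
        resid = variances - (slope * means + intercept)
        dof = max(len(means) - 2, 1)
        scale = float((w * resid ** 2).sum()) / dof
        cov = scale * np.linalg.inv(XtWX)
        slope_sd, intercept_sd = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    return max(slope, 0.0), max(intercept, 0.0), slope_sd, intercept_sd, r2


def _binned_initial_selection(
    means: np.ndarray, variances: np.ndarray, quantile: float
) -> np.ndarray:
    """Level-balanced initial patch selection: within each patch-mean bin,
    keep the lowest-variance ``quantile`` fraction."""
    n = len(means)
    n_bins = int(np.clip(n // 10, 2, 8))
    edges = np.quantile(means, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    bins = np.clip(np.searchsorted(edges, means, side="right") - 1, 0, len(edges) - 2)
    keep: list[int] = []
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        k, _ = _lowest_fraction(variances[idx], quantile)
        keep.extend(idx[k].tolist())
    return np.sort(np.asarray(keep, dtype=int))


def estimate_noise_params(
    noisy: ImageGrid,
    patch_size_px: int = DEFAULT_PATCH_SIZE,
    homogeneity_quantile: float = DEFAULT_HOMOGENEITY_QUANTILE,
    offset_hu: float = DEFAULT_OFFSET_HU,
    clean: Optional[ImageGrid] = None,
) -> tuple[NoiseParams, PatchEstimateDiagnostics]:
    """Estimate (alpha, sigma) from a noisy image by variance-mean regression.

    Single-image estimation is the default.  When a matching ``clean`` image
    is supplied, patch variances are computed on the difference image
    instead (pair-based mode): structure then cannot leak into the variance
    at all.

    Selection follows the level-balanced + trimmed scheme described in the
    module docstring; ``homogeneity_quantile`` controls the initial
    within-bin selection.  ``alpha`` is reported in the shifted frame
    ``p + offset_hu``, recorded in the diagnostics.
    """
    if patch_size_px < 4:
        raise EstimationInfeasibleError(f"patch_size_px must be >= 4, got {patch_size_px}")
    if not (0 < homogeneity_quantile <= 1):
        raise EstimationInfeasibleError(
            f"homogeneity_quantile must be in (0, 1], got {homogeneity_quantile}")

    coords = _air_excluded_coords(noisy.pixels, patch_size_px)
    if len(coords) < 2:
        raise EstimationInfeasibleError(
            f"fewer than 2 usable {patch_size_px}x{patch_size_px} patches in a "
            f"{noisy.height}x{noisy.width} image")

    if clean is not None:
        if clean.pixels.shape != noisy.pixels.shape:
            raise EstimationInfeasibleError("clean and noisy images must share dimensions")
        _, variances = _patch_moments(noisy.pixels - clean.pixels, coords, patch_size_px)
        means, _ = _patch_moments(noisy.pixels, coords, patch_size_px)
        means = means + offset_hu
    else:
        means, variances = _patch_moments(noisy.pixels, coords, patch_size_px)
        means = means + offset_hu

    # initial level-balanced selection, then one-sided trim refinement
    keep = _binned_initial_selection(means, variances, homogeneity_quantile)
    rel_sd = math.sqrt(2.0 / (patch_size_px * patch_size_px - 3))
    for _ in range(_MAX_TRIM_ITER):
        if np.ptp(means[keep]) <= 1.0:
            break
        alpha, sigma2, *_ = fit_variance_mean_line(means[keep], variances[keep])
        expected = alpha * means + sigma2
        floor = max(float(np.median(np.abs(expected))), 1e-12)
        expected = np.maximum(expected, 0.1 * floor)
        new_keep = np.flatnonzero((variances - expected) / (expected * rel_sd) < _TRIM_SD)
        if len(new_keep) < 2 or np.array_equal(new_keep, keep):
            break
        keep = new_keep

    m_sel, v_sel = means[keep], variances[keep]
    if len(keep) < 2:
        raise EstimationInfeasibleError("fewer than 2 patches survive homogeneity selection")

    diag = PatchEstimateDiagnostics(
        patch_size_px=patch_size_px,
        n_patches_used=len(keep),
        homogeneity_threshold=_TRIM_SD,
        regression_r2=0.0,
        patch_stats=list(zip(m_sel.tolist(), v_sel.tolist())),
        offset_hu=offset_hu,
    )

    if np.ptp(m_sel) <= 1.0:
        # all patch means within one HU: the slope is unidentifiable
        warnings.warn(
            "patch means span <= 1 HU; returning a sigma-only estimate with "
            "alpha marked unreliable",
            IllConditionedSlopeWarning,
        )
        sigma2 = max(float(np.mean(v_sel)), 0.0)
        sigma = math.sqrt(sigma2)
        sigma2_sd = float(np.std(v_sel, ddof=1) / math.sqrt(len(v_sel))) if len(v_sel) > 1 else 0.0
        sigma_sd = sigma2_sd / (2 * sigma) if sigma > 0 else float("nan")
        diag.alpha_reliable = False
        params = NoiseParams(alpha=0.0, sigma=sigma, alpha_sd=float("nan"), sigma_sd=sigma_sd)
        return params, diag

    alpha, sigma2, alpha_sd, sigma2_sd, r2 = fit_variance_mean_line(m_sel, v_sel)
    sigma = math.sqrt(sigma2)
    # delta method for sigma = sqrt(intercept); undefined at sigma == 0
    sigma_sd = sigma2_sd / (2 * sigma) if sigma > 0 else float("nan")
    diag.regression_r2 = r2
    params = NoiseParams(alpha=alpha, sigma=sigma, alpha_sd=alpha_sd, sigma_sd=sigma_sd)
    return params, diag


def spawn_child_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` deterministic child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]
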