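"""The nine full-reference and ROI-based image-quality metrics.

Three evaluation categories group the metrics:

* noise & signal fidelity — SNR, PSNR, nRMSE, CNR;
* structural similarity — SSIM, FSIM, UQI;
* edge sharpness & structural distortion — GMSD, gradient magnitude (GM).

SSIM and UQI are computed in their *global-statistic* form (means, variances
and covariance taken over the whole image); a sliding-window mean SSIM is
available behind a flag but is not the default.  GMSD uses Prewitt gradients
(per its original formulation) and GM uses Sobel; both operators are
selectable.  All convolutions use reflect padding to avoid spurious
phantom-edge gradients.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateNoiseError,
    GeometryError,
    UndefinedMetricError,
    ZeroDynamicRangeError,
)
from .io_formats import ImageGrid
from .phasecong import DEFAULT_PC_CONFIG, PhaseCongruencyConfig, phase_congruency

log = logging.getLogger("ctiq")

CATEGORY_NOISE = "noise_signal"
CATEGORY_STRUCT = "structural_similarity"
CATEGORY_EDGE = "edge_structure"

METRIC_CATEGORIES = {
    "snr": CATEGORY_NOISE,
    "psnr": CATEGORY_NOISE,
    "nrmse": CATEGORY_NOISE,
    "cnr": CATEGORY_NOISE,
    "ssim": CATEGORY_STRUCT,
    "fsim": CATEGORY_STRUCT,
    "uqi": CATEGORY_STRUCT,
    "gmsd": CATEGORY_EDGE,
    "gm": CATEGORY_EDGE,
}


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Roi:
    """A rectangular region [r0, r0+h) x [c0, c0+w) with a role."""

    label: str
    role: str  # signal | background | lesion
    r0: int
    c0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.role not in ("signal", "background", "lesion"):
            raise GeometryError(f"unknown ROI role {self.role!r}")
        if self.height < 1 or self.width < 1:
            raise GeometryError(f"ROI {self.label!r} has non-positive size")

    def extract(self, image: ImageGrid) -> np.ndarray:
        if (self.r0 < 0 or self.c0 < 0
                or self.r0 + self.height > image.height
                or self.c0 + self.width > image.width):
            raise GeometryError(
                f"ROI {self.label!r} [{self.r0}:{self.r0 + self.height}, "
                f"{self.c0}:{self.c0 + self.width}] lies outside the "
                f"{image.height}x{image.width} image")
        return image.pixels[self.r0:self.r0 + self.height, self.c0:self.c0 + self.width]


@dataclass
class RoiSet:
    """Named ROIs; 100x100 px is the conventional default size."""

    rois: list[Roi]

    def by_role(self, role: str) -> list[Roi]:
        return [r for r in self.rois if r.role == role]


@dataclass(frozen=True)
class GradientMasks:
    """A derivative-mask pair; ``hy`` is the transpose of ``hx`` and each
    mask's entries sum to zero."""

    hx: np.ndarray
    hy: np.ndarray
    name: str

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.hx))) > 1e-12 or abs(float(np.sum(self.hy))) > 1e-12:
            raise ValueError("gradient mask entries must sum to 0")
        if not np.allclose(self.hy, self.hx.T):
            raise ValueError("hy must be the transpose of hx")

    @classmethod
    def sobel(cls) -> "GradientMasks":
        hx = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
        return cls(hx=hx, hy=hx.T, name="sobel")

    @classmethod
    def prewitt(cls) -> "GradientMasks":
        # scaled by 1/3 per the original GMSD formulation
        hx = np.array([[1.0, 0.0, -1.0], [1.0, 0.0, -1.0], [1.0, 0.0, -1.0]]) / 3.0
        return cls(hx=hx, hy=hx.T, name="prewitt")

    def unit_normalized(self) -> "GradientMasks":
        """Masks scaled so the absolute entries sum to 1 (used by the GM score)."""
        norm = float(np.sum(np.abs(self.hx)))
        return GradientMasks(hx=self.hx / norm, hy=self.hy / norm, name=f"{self.name}-unit")


@dataclass
class MetricConstants:
    """Stabilising constants shared by the full-reference metrics.

    ``L`` is the dynamic range entering PSNR and the SSIM constants; when
    ``None`` it defaults to the reference image's max - min (the natural
    choice for signed HU data; override with e.g. 4096 for a fixed CT
    window).  ``eps_gmsd`` defaults to 0.0026 * L^2, scaled to the working
    intensity range; ``eps1_fsim``/``eps2_fsim`` live on the PC and
    normalised-gradient scales respectively.
    """

    L: Optional[float] = None
    k1: float = 0.01
    k2: float = 0.03
    eps_gmsd: Optional[float] = None
    eps1_fsim: float = 1e-4
    eps2_fsim: float = 1e-3
    gradient_masks: GradientMasks = field(default_factory=GradientMasks.sobel)
    gmsd_masks: GradientMasks = field(default_factory=GradientMasks.prewitt)
    pc_config: PhaseCongruencyConfig = DEFAULT_PC_CONFIG

    def resolve_L(self, reference: ImageGrid) -> float:
        if self.L is not None:
            if self.L <= 0:
                raise ValueError("L must be positive")
            return float(self.L)
        rng = float(np.ptp(reference.pixels))
        return rng if rng > 0 else 1.0

    def c1c2(self, L: float) -> tuple[float, float]:
        return (self.k1 * L) ** 2, (self.k2 * L) ** 2

    def resolve_eps_gmsd(self, L: float) -> float:
        return float(self.eps_gmsd) if self.eps_gmsd is not None else 0.0026 * L ** 2


@dataclass
class MetricValue:
    """One computed metric with its category and input provenance."""

    name: str
    value: float
    category: str
    inputs: tuple[str, ...] = ()
    flag: Optional[str] = None  # e.g. "identical_images" for the PSNR sentinel


def _check_same_shape(reference: ImageGrid, test: ImageGrid) -> None:
    if reference.pixels.shape != test.pixels.shape:
        raise GeometryError(
            f"image dimensions differ: {reference.pixels.shape} vs {test.pixels.shape}")


# ---------------------------------------------------------------------------
# noise & signal fidelity


def compute_snr(image: ImageGrid, rois: RoiSet) -> MetricValue:
    """SNR = 10 log10(M^2 / beta^2); M is the signal-ROI mean, beta the
    background-ROI SD."""
    signal = rois.by_role("signal")
    background = rois.by_role("background")
    if not signal or not background:
        raise GeometryError("SNR needs at least one signal and one background ROI")
    M = float(np.mean(np.concatenate([r.extract(image).ravel() for r in signal])))
    beta = float(np.std(np.concatenate([r.extract(image).ravel() for r in background])))
    if beta == 0:
        raise DegenerateNoiseError("background ROI is constant: SNR undefined (beta = 0)")
    value = 10.0 * math.log10(M ** 2 / beta ** 2)
    return MetricValue("snr", value, CATEGORY_NOISE, (image.provenance,))


def compute_psnr(reference: ImageGrid, test: ImageGrid,
                 constants: Optional[MetricConstants] = None) -> MetricValue:
    """PSNR = 20 log10(L / sqrt(E)); identical images yield an explicit
    +infinity sentinel rather than a numeric overflow."""
    constants = constants or MetricConstants()
    _check_same_shape(reference, test)
    L = constants.resolve_L(reference)
    E = float(np.mean((reference.pixels - test.pixels) ** 2))
    if E == 0:
        return MetricValue("psnr", math.inf, CATEGORY_NOISE,
                           (reference.provenance, test.provenance),
                           flag="identical_images")
    value = 20.0 * math.log10(L / math.sqrt(E))
    return MetricValue("psnr", value, CATEGORY_NOISE,
                       (reference.provenance, test.provenance))


def compute_nrmse(reference: ImageGrid, test: ImageGrid) -> MetricValue:
    """RMSE divided by the reference's dynamic range."""
    _check_same_shape(reference, test)
    dynamic_range = float(np.ptp(reference.pixels))
    if dynamic_range == 0:
        raise ZeroDynamicRangeError("reference image is flat: nRMSE undefined")
    rmse = math.sqrt(float(np.mean((test.pixels - reference.pixels) ** 2)))
    return MetricValue("nrmse", rmse / dynamic_range, CATEGORY_NOISE,
                       (reference.provenance, test.provenance))


def compute_cnr(image: ImageGrid, rois: RoiSet) -> list[MetricValue]:
    """|It - Ib| / sqrt(sigma_t^2 + sigma_b^2), one value per lesion ROI.

    The absolute difference keeps the sign convention independent of material
    ordering.
    """
    lesions = rois.by_role("lesion")
    background = rois.by_role("background")
    if not lesions:
        raise GeometryError("CNR needs at least one lesion ROI")
    if len(background) != 1:
        raise GeometryError(f"CNR needs exactly one background ROI, got {len(background)}")
    bg = background[0].extract(image)
    Ib, var_b = float(np.mean(bg)), float(np.var(bg))
    out = []
    for roi in lesions:
        px = roi.extract(image)
        It, var_t = float(np.mean(px)), float(np.var(px))
        if var_t + var_b == 0:
            raise DegenerateNoiseError(
                f"lesion ROI {roi.label!r} and background are both constant: CNR undefined")
        value = abs(It - Ib) / math.sqrt(var_t + var_b)
        out.append(MetricValue(f"cnr_{roi.label}", value, CATEGORY_NOISE, (image.provenance,)))
    return out


# ---------------------------------------------------------------------------
# structural similarity


def compute_ssim(reference: ImageGrid, test: ImageGrid,
                 constants: Optional[MetricConstants] = None,
                 windowed: bool = False, window: int = 8) -> MetricValue:
    """Global-statistic SSIM (whole-image means/variances/covariance).

    ``windowed=True`` switches to a mean of per-window global SSIM values
    over a non-overlapping tiling — provided for comparison, not the default.
    """
    constants = constants or MetricConstants()
    _check_same_shape(reference, test)
    L = constants.resolve_L(reference)
    c1, c2 = constants.c1c2(L)

    def _ssim(a: np.ndarray, b: np.ndarray) -> float:
        mu_r, mu_s = float(a.mean()), float(b.mean())
        var_r, var_s = float(a.var()), float(b.var())
        cov = float(((a - mu_r) * (b - mu_s)).mean())
        return (((2 * mu_r * mu_s + c1) * (2 * cov + c2))
                / ((mu_r ** 2 + mu_s ** 2 + c1) * (var_r + var_s + c2)))

    if windowed:
        h, w = reference.pixels.shape
        vals = [
            _ssim(reference.pixels[r:r + window, c:c + window],
                  test.pixels[r:r + window, c:c + window])
            for r in range(0, h - window + 1, window)
            for c in range(0, w - window + 1, window)
        ]
        value = float(np.mean(vals))
    else:
        value = _ssim(reference.pixels, test.pixels)
    return MetricValue("ssim", value, CATEGORY_STRUCT,
                       (reference.provenance, test.provenance))


def compute_uqi(reference: ImageGrid, test: ImageGrid) -> MetricValue:
    """Universal Quality Index: luminance term times structure term, with no
    stabilising constants."""
    _check_same_shape(reference, test)
    x, y = reference.pixels, test.pixels
    xm, ym = float(x.mean()), float(y.mean())
    var_x, var_y = float(x.var()), float(y.var())
    cov = float(((x - xm) * (y - ym)).mean())
    if xm ** 2 + ym ** 2 == 0 or var_x + var_y == 0:
        raise UndefinedMetricError("UQI undefined: zero mean energy or zero total variance")
    value = (2 * xm * ym / (xm ** 2 + ym ** 2)) * (2 * cov / (var_x + var_y))
    return MetricValue("uqi", value, CATEGORY_STRUCT,
                       (reference.provenance, test.provenance))


# ---------------------------------------------------------------------------
# gradients, GM, GMSD, FSIM


def compute_gradient_map(image: ImageGrid | np.ndarray,
                         masks: Optional[GradientMasks] = None) -> np.ndarray:
    """Per-pixel gradient magnitude sqrt((F*Hx)^2 + (F*Hy)^2), reflect
    boundary handling, same shape as the input."""
    masks = masks or GradientMasks.sobel()
    px = image.pixels if isinstance(image, ImageGrid) else np.asarray(image, dtype=float)
    gx = ndimage.convolve(px, masks.hx, mode="reflect")
    gy = ndimage.convolve(px, masks.hy, mode="reflect")
    return np.sqrt(gx ** 2 + gy ** 2)


def compute_gm_score(image: ImageGrid,
                     masks: Optional[GradientMasks] = None) -> MetricValue:
    """Scalar gradient-magnitude score.

    The image is first normalised to [0, 1] by its own dynamic range and the
    masks are scaled to unit absolute sum, so the score is invariant to
    affine intensity rescaling; a flat image scores 0 by convention.
    """
    masks = (masks or GradientMasks.sobel()).unit_normalized()
    rng = float(np.ptp(image.pixels))
    if rng == 0:
        log.info("compute_gm_score: flat image, returning 0 by convention")
        return MetricValue("gm", 0.0, CATEGORY_EDGE, (image.provenance,), flag="flat_image")
    normed = (image.pixels - float(image.pixels.min())) / rng
    value = float(np.mean(compute_gradient_map(normed, masks)))
    return MetricValue("gm", value, CATEGORY_EDGE, (image.provenance,))


def compute_gmsd(reference: ImageGrid, test: ImageGrid,
                 constants: Optional[MetricConstants] = None) -> MetricValue:
    """Gradient-magnitude similarity deviation: the population SD of the
    per-pixel similarity map (2 Gx Gy + eps)/(Gx^2 + Gy^2 + eps)."""
    constants = constants or MetricConstants()
    _check_same_shape(reference, test)
    L = constants.resolve_L(reference)
    eps = constants.resolve_eps_gmsd(L)
    gx = compute_gradient_map(reference, constants.gmsd_masks)
    gy = compute_gradient_map(test, constants.gmsd_masks)
    sim = (2.0 * gx * gy + eps) / (gx ** 2 + gy ** 2 + eps)
    value = float(np.std(sim))  # population SD
    return MetricValue("gmsd", value, CATEGORY_EDGE,
                       (reference.provenance, test.provenance))


def compute_phase_congruency(image: ImageGrid | np.ndarray,
                             config: PhaseCongruencyConfig = DEFAULT_PC_CONFIG) -> np.ndarray:
    """Per-pixel phase-congruency map in [0, 1] (see :mod:`ctiq.phasecong`)."""
    px = image.pixels if isinstance(image, ImageGrid) else np.asarray(image, dtype=float)
    return phase_congruency(px, config)


def compute_fsim(reference: ImageGrid, test: ImageGrid,
                 constants: Optional[MetricConstants] = None) -> MetricValue:
    """Feature similarity index from phase congruency (primary feature) and
    gradient magnitude (auxiliary feature), pooled with max(PC1, PC2) weights.

    Gradients are computed on images normalised by the reference's dynamic
    range so that ``eps2_fsim`` lives on a fixed [0, 1] gradient scale.
    """
    constants = constants or MetricConstants()
    _check_same_shape(reference, test)
    pc1 = compute_phase_congruency(reference, constants.pc_config)
    pc2 = compute_phase_congruency(test, constants.pc_config)

    L = constants.resolve_L(reference)
    ref_min = float(reference.pixels.min())
    ref_n = (reference.pixels - ref_min) / L
    test_n = (test.pixels - ref_min) / L
    g1 = compute_gradient_map(ref_n, constants.gradient_masks)
    g2 = compute_gradient_map(test_n, constants.gradient_masks)

    e1, e2 = constants.eps1_fsim, constants.eps2_fsim
    sp = (2 * pc1 * pc2 + e1) / (pc1 ** 2 + pc2 ** 2 + e1)
    sg = (2 * g1 * g2 + e2) / (g1 ** 2 + g2 ** 2 + e2)
    weight = np.maximum(pc1, pc2)
    wsum = float(weight.sum())
    if wsum == 0:
        raise UndefinedMetricError("FSIM undefined: both images are featureless (all PC weights 0)")
    value = float((weight * sp * sg).sum() / wsum)
    return MetricValue("fsim", value, CATEGORY_STRUCT,
                       (reference.provenance, test.provenance))
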