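"""Synthetic stand-ins for the three AAPM CIRS-610 phantom sections.

The physical phantom offers a linearity section (circular inserts of distinct
HU for signal/noise assessment), a high-resolution section (bar patterns of
increasing spatial frequency), and an artifact section (high-HU inserts in a
uniform body).  These generators reproduce the *functional* geometry of each
section — not a metrological replica: insert materials are not published, so
the default insert HU values are documented placeholders, and no streak or
beam-hardening physics is simulated.

Reconstruction-strength surrogates stand in for the proprietary deep-learning
reconstruction presets of commercial scanners, which have no published
equations: "smoother" presets are Gaussian blurs of decreasing strength and
the "sharper" preset adds an unsharp mask, producing a strict smooth-to-sharp
ordering that the pipeline tests rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .io_formats import ImageGrid

AIR_HU = -1000.0

# Default insert HU values for the linearity section.  The real phantom's
# materials are unpublished; these five are placeholders spanning lung-ish to
# bone-ish attenuation and are fully config-exposed.
DEFAULT_LINEARITY_HU = (-200.0, -100.0, 0.0, 120.0, 990.0)

#: Default body (disk) HU.  Slightly above water so that ROI means are
#: nonzero and SNR is well defined on every module.
DEFAULT_BODY_HU = 50.0

_SUPERSAMPLE = 4  # anti-aliasing factor: draw at 4x, then area-average


@dataclass(frozen=True)
class Insert:
    """One circular insert: center (row, col) in px, radius in px, HU, label."""

    center: tuple[float, float]
    radius_px: float
    hu_value: float
    label: str


@dataclass(frozen=True)
class BarPattern:
    """One bar-pattern region for the high-resolution section.

    ``region`` is ``(r0, c0, height, width)`` in base-image pixels; bars
    alternate along columns with period ``2 * bar_width_px``.
    """

    region: tuple[int, int, int, int]
    bar_width_px: int
    hu_contrast: float


@dataclass
class PhantomSpec:
    """Geometry and HU assignments for one phantom section."""

    module: str
    size_px: tuple[int, int] = (512, 512)
    body_hu: float = DEFAULT_BODY_HU
    inserts: list[Insert] = field(default_factory=list)
    bar_patterns: list[BarPattern] = field(default_factory=list)
    blur_fwhm_px: float = 2.0
    disk_center: Optional[tuple[float, float]] = None
    disk_radius_px: Optional[float] = None

    def __post_init__(self) -> None:
        if self.module not in ("linearity", "high_resolution", "artifact"):
            raise GeometryError(f"unknown phantom module {self.module!r}")
        h, w = self.size_px
        if self.disk_center is None:
            self.disk_center = ((h - 1) / 2.0, (w - 1) / 2.0)
        if self.disk_radius_px is None:
            self.disk_radius_px = 0.449 * min(h, w)
        if self.blur_fwhm_px < 0:
            raise GeometryError("blur_fwhm_px must be nonnegative")
        labels = [ins.label for ins in self.inserts]
        if len(set(labels)) != len(labels):
            raise GeometryError(f"insert labels must be unique, got {labels}")
        self._validate_geometry()

    def _validate_geometry(self) -> None:
        cy, cx = self.disk_center
        for ins in self.inserts:
            d = math.hypot(ins.center[0] - cy, ins.center[1] - cx)
            if d + ins.radius_px > self.disk_radius_px:
                raise GeometryError(
                    f"insert {ins.label!r} (r={ins.radius_px}) extends outside the "
                    f"phantom disk (center distance {d:.1f}, disk radius {self.disk_radius_px:.1f})"
                )
        for i, a in enumerate(self.inserts):
            for b in self.inserts[i + 1:]:
                d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < a.radius_px + b.radius_px:
                    raise GeometryError(f"inserts {a.label!r} and {b.label!r} overlap")


def default_spec(module: str, size_px: tuple[int, int] = (512, 512),
                 body_hu: float = DEFAULT_BODY_HU) -> PhantomSpec:
    """Build the default specification for a phantom section.

    All positions scale with the image size so that smaller test images keep
    the same layout.  At the default 512x512:

    * linearity — five r=71 px inserts on a ring of radius 150 px
      (HU -200, -100, 0, 120, 990), each large enough to hold a centred
      100x100 ROI;
    * high_resolution — five 56x56 bar groups (bar widths 8, 6, 4, 3, 2 px,
      +400 HU contrast) in the upper half of the disk;
    * artifact — two high-HU (990) r=40 px inserts left and right of centre.
    """
    h, w = size_px
    s = min(h, w) / 512.0
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    if module == "linearity":
        ring, radius = 150.0 * s, 71.0 * s
        inserts = []
        for k, hu in enumerate(DEFAULT_LINEARITY_HU):
            ang = math.radians(90.0 + 72.0 * k)
            inserts.append(Insert(
                center=(cy - ring * math.sin(ang), cx + ring * math.cos(ang)),
                radius_px=radius, hu_value=hu, label=f"insert{k + 1}",
            ))
        return PhantomSpec(module=module, size_px=size_px, body_hu=body_hu, inserts=inserts)

    if module == "high_resolution":
        widths = (8, 6, 4, 3, 2)
        box = int(round(56 * s))
        row = int(round(cy - 106 * s))
        bars = []
        for k, bw in enumerate(widths):
            col = int(round(cx + (k - 2) * 70 * s))
            bars.append(BarPattern(
                region=(row - box // 2, col - box // 2, box, box),
                bar_width_px=max(1, int(round(bw * s))),
                hu_contrast=400.0,
            ))
        return PhantomSpec(module=module, size_px=size_px, body_hu=body_hu, bar_patterns=bars)

    if module == "artifact":
        radius, off = 40.0 * s, 120.0 * s
        inserts = [
            Insert(center=(cy, cx - off), radius_px=radius, hu_value=990.0, label="artifact_left"),
            Insert(center=(cy, cx + off), radius_px=radius, hu_value=990.0, label="artifact_right"),
        ]
        return PhantomSpec(module=module, size_px=size_px, body_hu=body_hu, inserts=inserts)

    raise GeometryError(f"unknown phantom module {module!r}")


def make_phantom(spec: PhantomSpec, seed: int = 0) -> ImageGrid:
    """Render a clean phantom image from ``spec``.

    Geometry is drawn at 4x resolution and area-averaged back down
    (anti-aliasing that keeps ROI means stable regardless of grid phase),
    then blurred by ``blur_fwhm_px`` to model finite system resolution.
    Rendering is fully deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic stages and recorded in the provenance.
    """
    h, w = spec.size_px
    ss = _SUPERSAMPLE
    # supersampled pixel centers, expressed in base-pixel coordinates
    rr = (np.arange(h * ss, dtype=np.float64)[:, None] + 0.5) / ss - 0.5
    cc = (np.arange(w * ss, dtype=np.float64)[None, :] + 0.5) / ss - 0.5
    cy, cx = spec.disk_center

    canvas = np.full((h * ss, w * ss), AIR_HU, dtype=np.float64)
    disk = (rr - cy) ** 2 + (cc - cx) ** 2 <= spec.disk_radius_px ** 2
    canvas[disk] = spec.body_hu

    for ins in spec.inserts:
        mask = (rr - ins.center[0]) ** 2 + (cc - ins.center[1]) ** 2 <= ins.radius_px ** 2
        canvas[mask] = ins.hu_value

    for bar in spec.bar_patterns:
        r0, c0, bh, bw = bar.region
        region = (rr >= r0) & (rr < r0 + bh) & (cc >= c0) & (cc < c0 + bw)
        phase = (np.floor((cc - c0) / bar.bar_width_px).astype(int) % 2) == 0
        canvas[region & phase & disk] = spec.body_hu + bar.hu_contrast

    img = canvas.reshape(h, ss, w, ss).mean(axis=(1, 3))
    if spec.blur_fwhm_px > 0:
        sigma = spec.blur_fwhm_px / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        img = ndimage.gaussian_filter(img, sigma=sigma, mode="nearest")
    return ImageGrid(img, provenance=f"synthetic-{spec.module}:clean:seed={seed}")


# ---------------------------------------------------------------------------
# reconstruction-surrogate presets


@dataclass(frozen=True)
class PresetSpec:
    """A reconstruction-strength surrogate.

    ``smooth_strength`` is the SD (px) of a Gaussian blur; ``sharpen_amount``
    is an unsharp-mask gain applied after any blur.  Both are nonnegative and
    named defaults keep one of the two dominant.
    """

    name: str
    smooth_strength: float = 0.0
    sharpen_amount: float = 0.0

    def __post_init__(self) -> None:
        if self.smooth_strength < 0 or self.sharpen_amount < 0:
            raise GeometryError("preset strengths must be nonnegative")


#: Named surrogate presets producing a strict smooth->sharp ordering.
DEFAULT_PRESETS = {
    "surrogate-smoother": PresetSpec("surrogate-smoother", smooth_strength=1.5),
    "surrogate-standard": PresetSpec("surrogate-standard", smooth_strength=1.0),
    "surrogate-sharper": PresetSpec("surrogate-sharper", smooth_strength=0.5, sharpen_amount=0.8),
    "surrogate-M": PresetSpec("surrogate-M", smooth_strength=1.25),
    "surrogate-H": PresetSpec("surrogate-H", smooth_strength=2.0),
}

_UNSHARP_SIGMA = 1.0  # px; fixed base scale of the unsharp mask


def apply_preset(image: ImageGrid, preset: PresetSpec) -> ImageGrid:
    """Apply a deterministic reconstruction surrogate to an image.

    With both strengths zero the output is pixel-identical to the input.
    Smoothing strictly reduces variance in homogeneous regions; sharpening
    strictly increases mean gradient magnitude near edges.
    """
    out = image.pixels
    if preset.smooth_strength > 0:
        out = ndimage.gaussian_filter(out, sigma=preset.smooth_strength, mode="nearest")
    if preset.sharpen_amount > 0:
        blurred = ndimage.gaussian_filter(out, sigma=_UNSHARP_SIGMA, mode="nearest")
        out = out + preset.sharpen_amount * (out - blurred)
    return image.with_pixels(out, provenance=f"{image.provenance}|{preset.name}")
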