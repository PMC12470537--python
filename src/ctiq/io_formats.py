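"""Image and configuration I/O.

All images travel through the pipeline as :class:`ImageGrid` — a 2-D array of
intensities in Hounsfield units (HU) with pixel-spacing metadata.  Supported
on-disk formats are single-frame CT DICOM (rescale slope/intercept honoured),
8/16-bit grayscale PNG with an explicit affine HU mapping, and raw ``.npy``
arrays (the only lossless route).

Coordinates are 0-based ``(row, col)`` with the row index increasing downward;
every rectangular region in the package uses half-open intervals
``[r0, r0+h) x [c0, c0+w)``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import ConfigError, FormatError

log = logging.getLogger("ctiq")

VALID_MODULES = ("linearity", "high_resolution", "artifact")


@dataclass
class ImageGrid:
    """A 2-D grayscale image in Hounsfield units.

    Parameters
    ----------
    pixels:
        2-D float array of finite HU values, at least 2x2.
    pixel_spacing_mm:
        (row, col) physical pixel size; both components positive.
    provenance:
        Free-text label describing where the image came from, e.g.
        ``"synthetic-linearity"`` or ``"dicom:/path/to/slice.dcm"``.
    """

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise FormatError(f"ImageGrid requires a 2-D array, got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise FormatError(f"ImageGrid must be at least 2x2, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("ImageGrid pixels must all be finite")
        sp = tuple(float(s) for s in self.pixel_spacing_mm)
        if len(sp) != 2 or sp[0] <= 0 or sp[1] <= 0:
            raise FormatError(f"pixel_spacing_mm must be a positive pair, got {self.pixel_spacing_mm}")
        self.pixel_spacing_mm = sp

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def with_pixels(self, pixels: np.ndarray, provenance: Optional[str] = None) -> "ImageGrid":
        """Return a copy holding ``pixels`` and optionally a new provenance label."""
        return ImageGrid(
            pixels=np.asarray(pixels, dtype=np.float64),
            pixel_spacing_mm=self.pixel_spacing_mm,
            provenance=self.provenance if provenance is None else provenance,
        )


# ---------------------------------------------------------------------------
# image I/O


def _detect_format(path: os.PathLike | str, format_hint: Optional[str]) -> str:
    if format_hint is not None:
        fmt = format_hint.lower()
        if fmt not in ("dicom", "png", "npy"):
            raise FormatError(f"unknown format hint {format_hint!r}; expected dicom/png/npy")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".dcm", ".dicom"):
        return "dicom"
    if suffix == ".png":
        return "png"
    if suffix == ".npy":
        return "npy"
    raise FormatError(f"cannot infer format of {path!r}; pass format_hint=dicom/png/npy")


def read_image(
    path: os.PathLike | str,
    format_hint: Optional[str] = None,
    *,
    hu_slope: Optional[float] = None,
    hu_intercept: Optional[float] = None,
    pixel_spacing_mm: Optional[tuple[float, float]] = None,
) -> ImageGrid:
    """Read an image file into HU.

    DICOM files use their rescale slope/intercept tags (overridable with
    ``hu_slope``/``hu_intercept``); PNG files *require* an explicit affine HU
    mapping ``HU = slope * stored + intercept`` because raw 8/16-bit gray
    levels are ambiguous; ``.npy`` arrays are taken to already be in HU.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    fmt = _detect_format(path, format_hint)

    if fmt == "npy":
        try:
            arr = np.load(path)
        except Exception as exc:  # noqa: BLE001 - wrap any loader failure
            raise FormatError(f"could not read npy file {path}: {exc}") from exc
        grid = ImageGrid(np.asarray(arr, dtype=np.float64),
                         pixel_spacing_mm=pixel_spacing_mm or (1.0, 1.0),
                         provenance=f"npy:{path}")
    elif fmt == "png":
        if hu_slope is None or hu_intercept is None:
            raise FormatError(
                f"PNG file {path} requires an explicit HU mapping: "
                "pass hu_slope and hu_intercept (HU = slope*stored + intercept)"
            )
        import imageio.v3 as iio

        try:
            raw = np.asarray(iio.imread(path))
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"could not read PNG file {path}: {exc}") from exc
        if raw.ndim == 3:  # collapse any accidental RGB(A) to gray
            raw = raw[..., 0]
        arr = hu_slope * raw.astype(np.float64) + hu_intercept
        grid = ImageGrid(arr, pixel_spacing_mm=pixel_spacing_mm or (1.0, 1.0),
                         provenance=f"png:{path}")
    else:  # dicom
        import pydicom

        try:
            ds = pydicom.dcmread(path)
            raw = ds.pixel_array.astype(np.float64)
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"could not read DICOM file {path}: {exc}") from exc
        if raw.ndim != 2:
            raise FormatError(f"DICOM file {path} is not a single-frame 2-D slice")
        if hu_slope is not None and hu_intercept is not None:
            slope, intercept = float(hu_slope), float(hu_intercept)
        else:
            if not hasattr(ds, "RescaleSlope") or not hasattr(ds, "RescaleIntercept"):
                raise FormatError(
                    f"DICOM file {path} lacks RescaleSlope/RescaleIntercept; "
                    "pass hu_slope and hu_intercept to define the HU mapping explicitly"
                )
            slope, intercept = float(ds.RescaleSlope), float(ds.RescaleIntercept)
        spacing = pixel_spacing_mm
        if spacing is None:
            spacing = tuple(float(v) for v in getattr(ds, "PixelSpacing", (1.0, 1.0)))
        grid = ImageGrid(slope * raw + intercept, pixel_spacing_mm=spacing,
                         provenance=f"dicom:{path}")

    if not np.all(np.isfinite(grid.pixels)):  # pragma: no cover - guarded in ImageGrid
        raise FormatError(f"image {path} contains non-finite pixel values")
    log.info("read %s image %s (%dx%d)", fmt, path, grid.height, grid.width)
    return grid


def write_image(
    image: ImageGrid,
    path: os.PathLike | str,
    format: str,  # noqa: A002 - spec'd parameter name
    *,
    hu_slope: float = 1.0,
    hu_intercept: float = -1024.0,
) -> Path:
    """Write an image; ``npy`` is lossless, PNG inverts the HU mapping.

    PNG output stores ``round((HU - intercept)/slope)`` clipped to the 16-bit
    range; the mapping and whether clipping occurred are recorded in a JSON
    sidecar next to the file.  DICOM output writes a minimal single-frame CT
    dataset with integer-rounded HU and rescale tags (slope 1, intercept 0).
    """
    path = Path(path)
    fmt = format.lower()
    if fmt not in ("dicom", "png", "npy"):
        raise FormatError(f"unknown output format {format!r}")
    if not path.parent.exists():
        raise OSError(f"output directory {path.parent} does not exist")

    if fmt == "npy":
        np.save(path, image.pixels)
    elif fmt == "png":
        import imageio.v3 as iio

        stored = np.round((image.pixels - hu_intercept) / hu_slope)
        clipped = bool(np.any(stored < 0) or np.any(stored > 65535))
        if clipped:
            log.warning("write_image: HU values outside the PNG mapping range were clipped (%s)", path)
        stored = np.clip(stored, 0, 65535).astype(np.uint16)
        iio.imwrite(path, stored)
        sidecar = {
            "hu_slope": hu_slope,
            "hu_intercept": hu_intercept,
            "clipped": clipped,
            "pixel_spacing_mm": list(image.pixel_spacing_mm),
            "provenance": image.provenance,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    else:  # dicom
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.Rows, ds.Columns = image.height, image.width
        ds.PixelSpacing = [image.pixel_spacing_mm[0], image.pixel_spacing_mm[1]]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1
        ds.RescaleIntercept = 0
        stored = np.clip(np.round(image.pixels), -32768, 32767).astype(np.int16)
        ds.PixelData = stored.tobytes()
        ds.save_as(path, enforce_file_format=True)

    log.info("wrote %s image %s", fmt, path)
    return path


# ---------------------------------------------------------------------------
# evaluation configuration


@dataclass
class EvaluationConfig:
    """Validated description of one evaluation run.

    Replicates re-draw the injected noise only (the synthetic analogue of
    repeated acquisitions); three replicates are the default.
    """

    modules: list[str]
    presets: list  # list[PresetSpec]; typed loosely to avoid a circular import
    noise: "object"  # NoiseParams
    replicates: int = 3
    seed: int = 0
    image_size: tuple[int, int] = (512, 512)
    roi_size: int = 100
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.modules:
            raise ConfigError("config must list at least one phantom module")
        for m in self.modules:
            if m not in VALID_MODULES:
                raise ConfigError(f"unknown module {m!r}; allowed: {', '.join(VALID_MODULES)}")
        if int(self.replicates) < 1:
            raise ConfigError(f"replicates must be >= 1, got {self.replicates}")
        self.replicates = int(self.replicates)
        names = [p.name for p in self.presets]
        if len(set(names)) != len(names):
            raise ConfigError(f"preset names must be unique, got {names}")
        h, w = (int(v) for v in self.image_size)
        if h < 2 or w < 2:
            raise ConfigError(f"image_size must be at least 2x2, got {self.image_size}")
        self.image_size = (h, w)
        if int(self.roi_size) < 2:
            raise ConfigError(f"roi_size must be >= 2, got {self.roi_size}")
        self.roi_size = int(self.roi_size)

    def config_hash(self) -> str:
        """Stable hash of the configuration, for replayable run logging."""
        payload = {
            "modules": self.modules,
            "presets": [asdict(p) for p in self.presets],
            "noise": {"alpha": self.noise.alpha, "sigma": self.noise.sigma},
            "replicates": self.replicates,
            "seed": self.seed,
            "image_size": list(self.image_size),
            "roi_size": self.roi_size,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: os.PathLike | str) -> EvaluationConfig:
    """Load a YAML or JSON evaluation config, fill defaults, and validate."""
    from .noise_model import NoiseParams, BMI_NOISE_PRESETS
    from .phantom_synth import PresetSpec, DEFAULT_PRESETS

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such config file: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"could not parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping at top level")

    modules = raw.get("modules", ["linearity"])
    if isinstance(modules, str):
        modules = [modules]

    presets_raw = raw.get("presets", list(DEFAULT_PRESETS))
    presets = []
    for p in presets_raw:
        if isinstance(p, str):
            if p not in DEFAULT_PRESETS:
                raise ConfigError(
                    f"unknown preset name {p!r}; allowed named presets: {', '.join(DEFAULT_PRESETS)}"
                )
            presets.append(DEFAULT_PRESETS[p])
        elif isinstance(p, dict):
            presets.append(PresetSpec(
                name=p["name"],
                smooth_strength=float(p.get("smooth_strength", 0.0)),
                sharpen_amount=float(p.get("sharpen_amount", 0.0)),
            ))
        else:
            raise ConfigError(f"preset entries must be names or mappings, got {p!r}")

    noise_raw = raw.get("noise", "obese")
    if isinstance(noise_raw, str):
        if noise_raw not in BMI_NOISE_PRESETS:
            raise ConfigError(
                f"unknown noise preset {noise_raw!r}; allowed: {', '.join(BMI_NOISE_PRESETS)}"
            )
        noise = BMI_NOISE_PRESETS[noise_raw]
    else:
        noise = NoiseParams(alpha=float(noise_raw.get("alpha", 0.0)),
                            sigma=float(noise_raw.get("sigma", 0.0)))

    size = raw.get("image_size", 512)
    if isinstance(size, int):
        size = (size, size)

    return EvaluationConfig(
        modules=list(modules),
        presets=presets,
        noise=noise,
        replicates=raw.get("replicates", 3),
        seed=int(raw.get("seed", 0)),
        image_size=tuple(int(v) for v in size),
        roi_size=int(raw.get("roi_size", 100)),
        output_dir=str(raw.get("output_dir", "results")),
    )
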