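"""Desk-scale evaluation pipeline.

For each requested phantom module: render the clean phantom, inject
Poisson-Gaussian noise per replicate (replicates differ only by noise seed,
the synthetic analogue of repeated acquisitions), apply each reconstruction
surrogate, place the default ROI layout, compute all metrics, and average
over replicates.  Full-reference metrics compare against the clean phantom,
which plays the role of the reconstruction baseline; SNR and CNR use the ROI
layout on the processed image alone.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import GeometryError
from .io_formats import EvaluationConfig, ImageGrid
from .metrics import (
    METRIC_CATEGORIES,
    MetricConstants,
    Roi,
    RoiSet,
    compute_cnr,
    compute_fsim,
    compute_gm_score,
    compute_gmsd,
    compute_nrmse,
    compute_psnr,
    compute_snr,
    compute_ssim,
    compute_uqi,
)
from .noise_model import inject_noise
from .phantom_synth import PhantomSpec, apply_preset, default_spec, make_phantom

log = logging.getLogger("ctiq")


@dataclass
class MetricReport:
    """Long-format metric rows plus replicate averages and run metadata."""

    rows: pd.DataFrame  # module, preset, replicate, metric, value, category
    averages: pd.DataFrame  # module, preset, metric, category, mean
    metadata: dict = field(default_factory=dict)


def _centered_roi(label: str, role: str, center: tuple[float, float], size: int) -> Roi:
    r0 = int(round(center[0] - size / 2.0))
    c0 = int(round(center[1] - size / 2.0))
    return Roi(label=label, role=role, r0=r0, c0=c0, height=size, width=size)


def place_default_rois(module: str, spec: PhantomSpec, roi_size: int = 100) -> RoiSet:
    """Build the default ROI layout for a module.

    Linearity: one lesion ROI centred on each insert (shrunk to the circle's
    inscribed square, with a warning, when the insert cannot contain the full
    ROI), a background ROI at the disk centre, and a signal ROI centred on
    the highest-contrast insert.  Other modules: a signal ROI at the disk
    centre and a background ROI below it, both in uniform body material.
    """
    h, w = spec.size_px
    s = min(h, w) / 512.0
    cy, cx = spec.disk_center
    rois: list[Roi] = []

    if module == "linearity":
        if not spec.inserts:
            raise GeometryError("linearity ROI layout requires inserts")
        for ins in spec.inserts:
            size = roi_size
            inscribed = int(math.floor(ins.radius_px * math.sqrt(2.0)))
            if inscribed < roi_size:
                log.warning(
                    "insert %s (r=%.0f px) cannot contain a %dx%d ROI; shrinking to %dx%d",
                    ins.label, ins.radius_px, roi_size, roi_size, inscribed, inscribed)
                size = inscribed
            if size < 2:
                raise GeometryError(f"insert {ins.label!r} too small for any ROI")
            rois.append(_centered_roi(f"roi_{ins.label}", "lesion", ins.center, size))
        rois.append(_centered_roi("roi_background", "background", (cy, cx), roi_size))
        strongest = max(spec.inserts, key=lambda i: abs(i.hu_value - spec.body_hu))
        sig = next(r for r in rois if r.label == f"roi_{strongest.label}")
        rois.append(Roi("roi_signal", "signal", sig.r0, sig.c0, sig.height, sig.width))
    else:
        rois.append(_centered_roi("roi_signal", "signal", (cy, cx), roi_size))
        rois.append(_centered_roi("roi_background", "background", (cy + 114 * s, cx), roi_size))

    for roi in rois:
        if roi.r0 < 0 or roi.c0 < 0 or roi.r0 + roi.height > h or roi.c0 + roi.width > w:
            raise GeometryError(f"ROI {roi.label!r} would leave the {h}x{w} image")
    return RoiSet(rois=rois)


def _evaluate_one(clean: ImageGrid, processed: ImageGrid, rois: RoiSet,
                  constants: MetricConstants) -> list[tuple[str, float, str]]:
    """All metric (name, value, category) triples for one processed image."""
    out: list[tuple[str, float, str]] = []
    snr = compute_snr(processed, rois)
    out.append((snr.name, snr.value, snr.category))
    if rois.by_role("lesion"):
        for mv in compute_cnr(processed, rois):
            out.append((mv.name, mv.value, mv.category))
    psnr = compute_psnr(clean, processed, constants)
    out.append((psnr.name, psnr.value, psnr.category))
    for fn in (compute_nrmse,):
        mv = fn(clean, processed)
        out.append((mv.name, mv.value, mv.category))
    for fn in (compute_ssim, compute_gmsd, compute_fsim):
        mv = fn(clean, processed, constants)
        out.append((mv.name, mv.value, mv.category))
    uqi = compute_uqi(clean, processed)
    out.append((uqi.name, uqi.value, uqi.category))
    gm = compute_gm_score(processed, constants.gradient_masks)
    out.append((gm.name, gm.value, gm.category))
    return out


def run_evaluation(config: EvaluationConfig,
                   constants: Optional[MetricConstants] = None) -> MetricReport:
    """Run the full module x preset x replicate study and average replicates.

    Deterministic given the master seed: replicate noise seeds are spawned
    from it per (module, replicate).
    """
    constants = constants or MetricConstants()
    cfg_hash = config.config_hash()
    log.info("run_evaluation start: hash=%s seed=%d modules=%s",
             cfg_hash, config.seed, config.modules)
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(len(config.modules) * config.replicates)

    records = []
    for mi, module in enumerate(config.modules):
        spec = default_spec(module, size_px=config.image_size)
        clean = make_phantom(spec, seed=config.seed)
        rois = place_default_rois(module, spec, roi_size=config.roi_size)
        log.info("module %s: phantom generated, %d ROIs placed", module, len(rois.rois))
        for rep in range(config.replicates):
            child = children[mi * config.replicates + rep]
            noisy = inject_noise(clean, config.noise, seed=child)
            for preset in config.presets:
                processed = apply_preset(noisy, preset)
                try:
                    triples = _evaluate_one(clean, processed, rois, constants)
                except Exception as exc:
                    raise type(exc)(
                        f"stage=evaluate module={module} preset={preset.name} "
                        f"replicate={rep}: {exc}") from exc
                for name, value, category in triples:
                    records.append({
                        "module": module, "preset": preset.name, "replicate": rep,
                        "metric": name, "value": value, "category": category,
                    })
        log.info("module %s: %d replicates evaluated", module, config.replicates)

    rows = pd.DataFrame.from_records(records)
    averages = (rows.groupby(["module", "preset", "metric", "category"], as_index=False)
                ["value"].mean().rename(columns={"value": "mean"}))
    metadata = {
        "config_hash": cfg_hash,
        "master_seed": config.seed,
        "replicates": config.replicates,
        "noise": {"alpha": config.noise.alpha, "sigma": config.noise.sigma},
        "image_size": list(config.image_size),
        "constants": {
            "k1": constants.k1, "k2": constants.k2,
            "L": constants.L, "eps1_fsim": constants.eps1_fsim,
            "eps2_fsim": constants.eps2_fsim,
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    return MetricReport(rows=rows, averages=averages, metadata=metadata)


def render_report(report: MetricReport, out_dir: str | Path) -> list[Path]:
    """Write report.csv / report.json plus one summary table per category per
    module; returns the written paths."""
    if report.rows.empty:
        raise ValueError("cannot render an empty report")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    paths = []
    csv_path = out_dir / "report.csv"
    report.rows.to_csv(csv_path, index=False)  # default repr: shortest round-trip
    paths.append(csv_path)

    json_path = out_dir / "report.json"
    payload = {
        "metadata": report.metadata,
        "rows": report.rows.to_dict(orient="records"),
        "averages": report.averages.to_dict(orient="records"),
    }
    json_path.write_text(json.dumps(payload, indent=2, default=float))
    paths.append(json_path)

    for module in report.averages["module"].unique():
        sub_m = report.averages[report.averages["module"] == module]
        for category in sub_m["category"].unique():
            sub = sub_m[sub_m["category"] == category]
            table = sub.pivot(index="preset", columns="metric", values="mean")
            p = out_dir / f"summary_{module}_{category}.csv"
            table.to_csv(p)
            paths.append(p)
    log.info("render_report: wrote %d files to %s", len(paths), out_dir)
    return paths
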