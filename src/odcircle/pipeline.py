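"""End-to-end orchestration: locate -> segment -> (optionally) evaluate.

``analyze`` works on in-memory arrays and returns every intermediate the
stages produce; ``run_pipeline`` and ``batch`` wrap it with file I/O and
result serialization for the command-line interface.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .metrics import (
    GroundTruth,
    MetricsReport,
    evaluate_masks,
    jc_interval_table,
)
from .od_localization import ODCenter, intensity_image, locate, od_detector, vessel_overlay
from .od_segmentation import (
    CircleModel,
    SectorRadii,
    fit_disc,
    rasterize_circle,
)
from .preprocessing import WorkingImage, complement_green, detect_fov, load_image, normalize_scale
from .vessel_evidence import VesselEvidence, compute_vessel_evidence

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


@dataclass
class PipelineResult:
    """Everything one image run produces.

    The circle is reported in both the normalized (540-px retina) frame and,
    scaled by ``1/scale``, in original-image coordinates.
    """

    working: WorkingImage
    evidence: VesselEvidence
    center: ODCenter
    circle_norm: CircleModel
    circle_orig: CircleModel
    sector_radii: SectorRadii
    window_side: int


def analyze(rgb: np.ndarray, config: PipelineConfig | None = None) -> PipelineResult:
    """Run localization and segmentation on an in-memory RGB image."""
    cfg = config or PipelineConfig()
    t0 = time.perf_counter()
    working = normalize_scale(rgb, retina_diameter=cfg.retina_diameter)
    g_c = complement_green(working)
    evidence = compute_vessel_evidence(g_c, working.fov.mask, cfg)
    i = intensity_image(working)
    i_c = vessel_overlay(i, evidence.v_e, working.fov.mask, cfg.vessel_percentile)
    d_od = od_detector(i_c, cfg.detector_circle_radius, cfg.detector_rect)
    center = locate(d_od, evidence.combined_mask, working.fov, working.scale)
    circle_norm, sector_radii, _ = fit_disc(i, center, cfg)
    circle_orig = circle_norm.scaled(1.0 / working.scale)
    logger.info(
        "analyzed image in %.2fs (constrained=%s)",
        time.perf_counter() - t0,
        center.constrained,
    )
    return PipelineResult(
        working=working,
        evidence=evidence,
        center=center,
        circle_norm=circle_norm,
        circle_orig=circle_orig,
        sector_radii=sector_radii,
        window_side=cfg.crop_side,
    )


def load_truth_mask(path) -> np.ndarray:
    """Read a single-channel ground-truth mask; any nonzero pixel is inside."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def evaluate_result(result: PipelineResult, truth_mask: np.ndarray) -> MetricsReport:
    """Score one pipeline result against an original-frame truth mask."""
    gt = GroundTruth.from_mask(truth_mask)
    pred = rasterize_circle(result.circle_orig, truth_mask.shape)
    return evaluate_masks(pred, gt, c_exp=(result.center.row_orig, result.center.col_orig))


def result_record(result: PipelineResult, report: MetricsReport | None = None) -> dict:
    """Flatten one result (plus optional metrics) to a JSON-serializable dict."""
    record = {
        "center_row": result.center.row_orig,
        "center_col": result.center.col_orig,
        "center_row_normalized": result.center.row_norm,
        "center_col_normalized": result.center.col_norm,
        "constrained": result.center.constrained,
        "scale": result.working.scale,
        "radius": result.circle_orig.radius,
        "radius_normalized": result.circle_norm.radius,
        "circle_center_row": result.circle_orig.center[0],
        "circle_center_col": result.circle_orig.center[1],
        "sector_radii": result.sector_radii.as_dict(),
        "window_side": result.window_side,
    }
    if report is not None:
        record.update(
            d_star=report.d_star,
            success=bool(report.success),
            jc=report.jc,
            dc=report.dc,
            mad=report.mad,
            mad_normalized=report.mad * result.working.scale,
        )
    return record


def run_pipeline(
    image_path,
    config: PipelineConfig | None = None,
    truth_path=None,
) -> dict:
    """Process one image file; include metrics when a truth mask is given."""
    rgb = load_image(image_path)
    result = analyze(rgb, config)
    report = None
    if truth_path is not None:
        report = evaluate_result(result, load_truth_mask(truth_path))
    record = result_record(result, report)
    record["image"] = str(image_path)
    return record


def summarize(rows: list[dict]) -> dict:
    """Aggregate block over per-image rows that carry metrics."""
    scored = [r for r in rows if "jc" in r]
    if not scored:
        return {"n_images": len(rows), "n_scored": 0}
    mean = lambda key: float(np.mean([r[key] for r in scored]))  # noqa: E731
    table = jc_interval_table([r["jc"] for r in scored])
    return {
        "n_images": len(rows),
        "n_scored": len(scored),
        "success_rate": float(np.mean([r["success"] for r in scored])),
        "mean_d_star": mean("d_star"),
        "mean_jc": mean("jc"),
        "mean_dc": mean("dc"),
        "mean_mad": mean("mad"),
        "mean_mad_normalized": mean("mad_normalized"),
        "jc_intervals": {f"jc>={t:.2f}": frac for t, frac in table.items()},
    }


CSV_COLUMNS = ("image", "d_star", "success", "jc", "dc", "mad")


def batch(
    image_dir,
    config: PipelineConfig | None = None,
    truth_dir=None,
    csv_path=None,
    json_path=None,
) -> tuple[list[dict], dict]:
    """Process every image in a directory, pairing truth masks by file stem.

    Returns per-image rows and the aggregate summary; optionally writes the
    CSV of rows and the summary JSON.
    """
    image_dir = Path(image_dir)
    images = sorted(
        p for p in image_dir.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
    )
    if not images:
        raise FileNotFoundError(f"no images found in {image_dir}")
    truths: dict[str, Path] = {}
    if truth_dir is not None:
        truths = {
            p.stem: p
            for p in Path(truth_dir).iterdir()
            if p.suffix.lower() in IMAGE_EXTENSIONS
        }
    rows = []
    for path in images:
        truth_path = truths.get(path.stem)
        if truth_dir is not None and truth_path is None:
            logger.warning("no truth mask for %s; row skipped", path.name)
            continue
        rows.append(run_pipeline(path, config, truth_path))
    summary = summarize(rows)
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_COLUMNS)
            for row in rows:
                writer.writerow([row.get(c, "") for c in CSV_COLUMNS])
    if json_path is not None:
        Path(json_path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return rows, summary
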