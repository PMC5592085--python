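"""Shared fixtures: synthetic discs and the cached end-to-end battery run."""

from __future__ import annotations

import numpy as np
import pytest

from odcircle import pipeline, synthetic
from odcircle.config import PipelineConfig


def disc_image(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    value: float = 200.0,
    background: float = 0.0,
) -> np.ndarray:
    """Gray disc rasterized into a single-channel float image."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, background, dtype=np.float64)
    img[np.hypot(rr - center[0], cc - center[1]) <= radius] = value
    return img


def disc_rgb(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    value: int = 200,
) -> np.ndarray:
    """Gray disc replicated over three 8-bit channels."""
    gray = disc_image(shape, center, radius, value).astype(np.uint8)
    return np.stack([gray] * 3, axis=-1)


@pytest.fixture(scope="session")
def battery_results() -> list[dict]:
    """Full pipeline run over the default 50-image battery (master seed 0).

    Each record carries the metric report, the scale, the true disc center
    in the normalized frame and constraint-mask geometry, so localization
    and segmentation properties can all be checked from one run.
    """
    cfg = PipelineConfig()
    records = []
    for spec in synthetic.default_battery_specs(50, 0):
        rgb, gt = synthetic.generate(spec)
        result = pipeline.analyze(rgb, cfg)
        report = pipeline.evaluate_result(result, gt.mask)
        scale = result.working.scale
        true_center_norm = (gt.center[0] * scale, gt.center[1] * scale)
        combined = result.evidence.combined_mask
        if combined.any():
            pts = np.argwhere(combined)
            mask_to_center = float(
                np.hypot(pts[:, 0] - true_center_norm[0], pts[:, 1] - true_center_norm[1]).min()
            )
        else:
            mask_to_center = np.inf
        records.append(
            {
                "d_star": report.d_star,
                "success": report.success,
                "jc": report.jc,
                "dc": report.dc,
                "mad": report.mad,
                "mad_normalized": report.mad * scale,
                "constrained": result.center.constrained,
                "scale": scale,
                "disc_radius_norm": spec.disc_radius * scale,
                "combined_mask_to_center": mask_to_center,
                "center_in_truth": bool(
                    gt.mask[
                        int(round(result.center.row_orig)),
                        int(round(result.center.col_orig)),
                    ]
                ),
            }
        )
    return records
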