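"""Vessel enhancement and the density/convergence constraint mask.

The optic disc is the entry point of the major retinal vessels, so the disc
region shows both a high vessel density and a convergence of vessel
directions.  This module computes:

* ``V_E`` — white top-hat of the complemented green channel (bright, thin
  vessels on a suppressed background);
* ``V_D`` — vessel density, the difference between a narrow and a wide box
  mean of ``V_E``, max-normalized;
* ``V_C`` — vessel convergence, the smoothed count of pairwise intersections
  of straight lines fitted (Hough transform) to the Canny edges of ``V_E``,
  max-normalized;
* the binary masks of both at threshold 0.3 and their logical AND, the
  constraint mask restricting the brightness-based disc search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import canny
from skimage.morphology import white_tophat
from skimage.transform import hough_line, hough_line_peaks

from .config import PipelineConfig
from .filters import box_mean, disc_footprint, disc_mean


@dataclass
class VesselEvidence:
    """All intermediate maps of the vessel-evidence stage.

    ``v_e`` is the nonnegative enhancement map; ``v_d`` and ``v_c`` are
    max-normalized to [0, 1] (identically zero when no evidence exists);
    ``combined_mask`` is the pixelwise AND of the two binary masks.
    """

    v_e: np.ndarray
    v_d: np.ndarray
    v_c: np.ndarray
    v_d_mask: np.ndarray
    v_c_mask: np.ndarray
    combined_mask: np.ndarray


def _normalize_max(m: np.ndarray) -> np.ndarray:
    """Divide by the maximum; an all-zero map stays all-zero (0/0 -> 0)."""
    peak = m.max() if m.size else 0.0
    if peak <= 0:
        return np.zeros_like(m, dtype=np.float64)
    return m / peak


def enhance_vessels(g_c: np.ndarray, radius: int = 8) -> np.ndarray:
    """White top-hat of the complemented green channel.

    Input minus its morphological opening with a disc structuring element of
    the given radius: structures thinner than the disc (vessels) survive,
    larger smooth regions are removed.  Output is nonnegative.
    """
    g_c = np.asarray(g_c, dtype=np.float64)
    return white_tophat(g_c, footprint=disc_footprint(radius))


def vessel_density(
    v_e: np.ndarray,
    narrow: tuple[int, int] = (80, 40),
    wide: tuple[int, int] = (80, 120),
) -> np.ndarray:
    """Vessel density map: narrow box mean minus wide box mean of ``V_E``.

    The narrow kernel matches the vertically elongated vessel bundle at the
    disc; the wide kernel samples the horizontally flanking retina, where
    vessel density is much lower.  Negatives are clipped (only an excess of
    density is evidence) and the result is divided by its maximum.
    """
    diff = box_mean(v_e, narrow) - box_mean(v_e, wide)
    np.clip(diff, 0.0, None, out=diff)
    return _normalize_max(diff)


def _hough_lines(
    edges: np.ndarray,
    top_k: int,
    min_distance: int,
    min_angle_deg: int,
    peak_floor: float = 0.2,
) -> list[tuple[float, float]]:
    """Top-K straight-line Hough peaks as (theta, rho) pairs.

    Line parametrization: ``col*cos(theta) + row*sin(theta) = rho``.
    Peaks below ``peak_floor`` times the accumulator maximum are dropped:
    curved vessels spread their votes over many cells, so the top peaks can
    sit well below half the maximum, but near-zero peaks are noise.
    """
    hspace, angles, dists = hough_line(edges)
    _, peak_angles, peak_dists = hough_line_peaks(
        hspace,
        angles,
        dists,
        min_distance=min_distance,
        min_angle=min_angle_deg,
        num_peaks=top_k,
        threshold=peak_floor * hspace.max(),
    )
    return list(zip(peak_angles, peak_dists))


def line_pair_intersections(
    lines: list[tuple[float, float]],
    shape: tuple[int, int],
    min_angle_deg: float = 3.0,
) -> np.ndarray:
    """Accumulator of pairwise line intersections inside the frame.

    For every unordered pair of ``(theta, rho)`` lines the intersection of
    ``col*cos(theta) + row*sin(theta) = rho`` is solved; +1 is accumulated at
    the nearest pixel when it lies inside ``shape``.  Pairs meeting at less
    than ``min_angle_deg`` are skipped as numerically unstable.
    """
    acc = np.zeros(shape, dtype=np.float64)
    min_angle = np.deg2rad(min_angle_deg)
    n = len(lines)
    for i in range(n):
        t1, r1 = lines[i]
        for j in range(i + 1, n):
            t2, r2 = lines[j]
            delta = abs(t1 - t2) % np.pi
            if min(delta, np.pi - delta) < min_angle:
                continue
            det = np.cos(t1) * np.sin(t2) - np.sin(t1) * np.cos(t2)
            col = (r1 * np.sin(t2) - r2 * np.sin(t1)) / det
            row = (r2 * np.cos(t1) - r1 * np.cos(t2)) / det
            ri, ci = int(round(row)), int(round(col))
            if 0 <= ri < shape[0] and 0 <= ci < shape[1]:
                acc[ri, ci] += 1.0
    return acc


def vessel_convergence(
    v_e: np.ndarray,
    fov_mask: np.ndarray | None = None,
    config: PipelineConfig | None = None,
) -> np.ndarray:
    """Vessel convergence map from Hough line intersections.

    Canny edges of the enhancement map are approximated by straight lines;
    each pixel of the raw map counts the pairwise line intersections landing
    on it.  A circular mean (radius 40) smooths the inherently noisy counts
    and the result is divided by its maximum.  Hysteresis thresholds are the
    70th/90th percentiles of the gradient magnitude inside the FOV, which
    keeps the detector resolution- and contrast-robust.
    """
    cfg = config or PipelineConfig()
    v_e = np.asarray(v_e, dtype=np.float64)
    mask = None if fov_mask is None else np.asarray(fov_mask, dtype=bool)
    region = mask if mask is not None else np.ones(v_e.shape, dtype=bool)

    smoothed = ndi.gaussian_filter(v_e, cfg.canny_sigma)
    grad = np.hypot(ndi.sobel(smoothed, axis=0), ndi.sobel(smoothed, axis=1))
    inside = grad[region]
    if inside.size == 0 or not np.any(inside > 0):
        return np.zeros_like(v_e)
    low, high = np.percentile(inside, (cfg.canny_low_pct, cfg.canny_high_pct))
    edges = canny(
        v_e,
        sigma=cfg.canny_sigma,
        low_threshold=low,
        high_threshold=high,
        mask=mask,
    )
    if not edges.any():
        return np.zeros_like(v_e)
    lines = _hough_lines(
        edges,
        cfg.hough_top_k,
        cfg.hough_min_distance,
        cfg.hough_min_angle_deg,
        cfg.hough_peak_floor,
    )
    acc = line_pair_intersections(lines, v_e.shape, cfg.intersection_min_angle_deg)
    return _normalize_max(disc_mean(acc, cfg.convergence_avg_radius))


def binarize_normalized(m: np.ndarray, threshold: float) -> np.ndarray:
    """Binary mask of pixels strictly above the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return np.asarray(m) > threshold


def combine_masks(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pixelwise logical AND of two binary rasters of identical shape."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a & b


def compute_vessel_evidence(
    g_c: np.ndarray,
    fov_mask: np.ndarray | None = None,
    config: PipelineConfig | None = None,
) -> VesselEvidence:
    """Run the full vessel-evidence stage on a complemented green channel."""
    cfg = config or PipelineConfig()
    v_e = enhance_vessels(g_c, cfg.tophat_radius)
    v_d = vessel_density(v_e, cfg.density_kernel_narrow, cfg.density_kernel_wide)
    v_c = vessel_convergence(v_e, fov_mask, cfg)
    v_d_mask = binarize_normalized(v_d, cfg.density_threshold)
    v_c_mask = binarize_normalized(v_c, cfg.convergence_threshold)
    return VesselEvidence(
        v_e=v_e,
        v_d=v_d,
        v_c=v_c,
        v_d_mask=v_d_mask,
        v_c_mask=v_c_mask,
        combined_mask=combine_masks(v_d_mask, v_c_mask),
    )
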