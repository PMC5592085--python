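"""Evaluation measures for disc localization and segmentation.

* normalized error distance ``D*`` — center error divided by the radius of a
  circle with the same area as the ground-truth mask;
* localization success — the estimated center pixel lies inside the
  ground-truth mask;
* Jaccard ``JC`` and Dice ``DC`` overlap coefficients (``DC = 2JC/(1+JC)``);
* ``MAD`` — symmetric mean of directed average nearest-neighbor distances
  between the two boundaries;
* the fraction of images reaching each JC level in
  {0.95, 0.90, 0.85, 0.80, 0.75, 0.70}.

All distances are in pixels of whichever frame the masks are supplied in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

_STRUCTURE_4 = ndi.generate_binary_structure(2, 1)

JC_THRESHOLDS = (0.95, 0.90, 0.85, 0.80, 0.75, 0.70)


@dataclass
class GroundTruth:
    """A ground-truth disc mask with derived boundary, centroid and radius.

    ``boundary`` lists the inner-boundary pixels (mask pixels with at least
    one 4-neighbor outside the mask); ``equivalent_radius`` is the radius of
    a circle with the same area as the mask.
    """

    mask: np.ndarray
    boundary: np.ndarray
    center: tuple[float, float]
    equivalent_radius: float

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "GroundTruth":
        mask = np.asarray(mask).astype(bool)
        area = int(mask.sum())
        if area == 0:
            raise ValueError("ground-truth mask is empty")
        eroded = ndi.binary_erosion(mask, structure=_STRUCTURE_4, border_value=0)
        boundary = np.argwhere(mask & ~eroded)
        center = ndi.center_of_mass(mask)
        return cls(
            mask=mask,
            boundary=boundary,
            center=(float(center[0]), float(center[1])),
            equivalent_radius=float(np.sqrt(area / np.pi)),
        )


@dataclass
class MetricsReport:
    """Localization and segmentation scores for one image."""

    d_star: float
    success: bool
    jc: float
    dc: float
    mad: float


def normalized_error_distance(c_exp: tuple[float, float], gt: GroundTruth) -> float:
    """Center localization error normalized by the area-equivalent radius."""
    if gt.equivalent_radius <= 0:
        raise ValueError("ground truth has no area")
    d = float(np.hypot(c_exp[0] - gt.center[0], c_exp[1] - gt.center[1]))
    return d / gt.equivalent_radius


def success(c_exp: tuple[float, float], gt: GroundTruth) -> bool:
    """Localization success: the center pixel lies inside the truth mask.

    The center is rounded to the nearest pixel; boundary pixels belong to
    the mask.  Out-of-frame centers count as failures.
    """
    row = int(round(c_exp[0]))
    col = int(round(c_exp[1]))
    if not (0 <= row < gt.mask.shape[0] and 0 <= col < gt.mask.shape[1]):
        return False
    return bool(gt.mask[row, col])


def _as_bool_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not a.any() and not b.any():
        raise ValueError("both masks are empty")
    return a, b


def jaccard(s_od: np.ndarray, s_truth: np.ndarray) -> float:
    """Intersection over union of the two masks."""
    a, b = _as_bool_pair(s_od, s_truth)
    union = int((a | b).sum())
    return int((a & b).sum()) / union


def dice(s_od: np.ndarray, s_truth: np.ndarray) -> float:
    """Twice the intersection over the sum of the mask sizes."""
    a, b = _as_bool_pair(s_od, s_truth)
    return 2 * int((a & b).sum()) / (int(a.sum()) + int(b.sum()))


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """(N, 2) array of inner-boundary pixel coordinates of a binary mask."""
    mask = np.asarray(mask).astype(bool)
    eroded = ndi.binary_erosion(mask, structure=_STRUCTURE_4, border_value=0)
    return np.argwhere(mask & ~eroded)


def mean_average_distance(b_od: np.ndarray, b_truth: np.ndarray) -> float:
    """Symmetric mean of directed average nearest-neighbor distances.

    ``MAD(A, B) = (mean_i d(a_i, B) + mean_j d(b_j, A)) / 2`` with
    ``d(p, S)`` the Euclidean distance from ``p`` to the nearest point of
    ``S``.  Symmetric in its arguments by construction.
    """
    a = np.asarray(b_od, dtype=np.float64)
    b = np.asarray(b_truth, dtype=np.float64)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != 2 or b.shape[1] != 2:
        raise ValueError("boundaries must be (N, 2) coordinate arrays")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty boundary set")
    d_ab, _ = cKDTree(b).query(a)
    d_ba, _ = cKDTree(a).query(b)
    return 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))


def evaluate_masks(
    pred_mask: np.ndarray,
    gt: GroundTruth | np.ndarray,
    c_exp: tuple[float, float] | None = None,
) -> MetricsReport:
    """Full metric report for one predicted mask against ground truth.

    ``c_exp`` defaults to the centroid of the predicted mask.
    """
    if not isinstance(gt, GroundTruth):
        gt = GroundTruth.from_mask(gt)
    pred_mask = np.asarray(pred_mask).astype(bool)
    if c_exp is None:
        if not pred_mask.any():
            raise ValueError("empty prediction and no explicit center")
        com = ndi.center_of_mass(pred_mask)
        c_exp = (float(com[0]), float(com[1]))
    jc = jaccard(pred_mask, gt.mask)
    return MetricsReport(
        d_star=normalized_error_distance(c_exp, gt),
        success=success(c_exp, gt),
        jc=jc,
        dc=dice(pred_mask, gt.mask),
        mad=mean_average_distance(boundary_points(pred_mask), gt.boundary),
    )


def jc_interval_table(
    reports: Sequence[MetricsReport] | Iterable[float],
    thresholds: Sequence[float] = JC_THRESHOLDS,
) -> dict[float, float]:
    """Fraction of images with ``JC >= t`` for each threshold ``t``.

    Accepts either metric reports or raw JC values; the fractions are
    non-increasing as the threshold rises (nested events).
    """
    jcs = np.array(
        [r.jc if isinstance(r, MetricsReport) else float(r) for r in reports],
        dtype=np.float64,
    )
    if jcs.size == 0:
        raise ValueError("empty report list")
    return {float(t): float((jcs >= t).mean()) for t in thresholds}
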