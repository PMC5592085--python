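"""Brightness-based optic disc detector and constrained-argmax localization.

The disc is the brightest roughly circular region of the summed-channel
intensity image, but the dark vessels crossing it depress its intensity.
Pixels with very high vessel-enhancement values are therefore painted with
the image maximum before filtering.  The detector is a difference of a
circular mean matching the disc size and a wide rectangular background mean;
its argmax restricted to the vessel constraint mask is the disc center.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .filters import box_mean, disc_mean
from .preprocessing import FOVMask, WorkingImage

logger = logging.getLogger(__name__)


@dataclass
class ODCenter:
    """Estimated optic disc center.

    ``(row_norm, col_norm)`` are integer pixel coordinates in the normalized
    540-px-retina frame; ``(row_orig, col_orig)`` map back to the original
    image (``row_norm / scale``).  ``constrained`` records whether the vessel
    constraint mask was nonempty and actually used.
    """

    row_norm: int
    col_norm: int
    row_orig: float
    col_orig: float
    detector_value: float
    constrained: bool


def intensity_image(w: WorkingImage | np.ndarray) -> np.ndarray:
    """Sum of the three RGB channels (real-valued, range 0-765)."""
    rgb = w.rgb if isinstance(w, WorkingImage) else np.asarray(w)
    return rgb[..., :3].astype(np.float64).sum(axis=-1)


def vessel_overlay(
    i: np.ndarray,
    v_e: np.ndarray,
    fov_mask: np.ndarray | None = None,
    percentile: float = 98.5,
) -> np.ndarray:
    """Compensate dark vessel pixels before disc detection.

    Pixels whose enhancement value strictly exceeds the given percentile of
    ``V_E`` are set to the maximum intensity, i.e. ``I_c = max(I, V_M)``.
    Both the percentile and the maximum are computed over FOV pixels only,
    so the dark surround does not distort either statistic.
    """
    i = np.asarray(i, dtype=np.float64)
    v_e = np.asarray(v_e, dtype=np.float64)
    if i.shape != v_e.shape:
        raise ValueError("intensity and enhancement rasters must share a shape")
    region = np.ones(i.shape, dtype=bool) if fov_mask is None else np.asarray(fov_mask, dtype=bool)
    cutoff = np.percentile(v_e[region], percentile)
    i_max = i[region].max()
    i_c = i.copy()
    i_c[v_e > cutoff] = i_max
    return i_c


def od_detector(
    i_c: np.ndarray,
    circle_radius: int = 40,
    rect: tuple[int, int] = (80, 160),
) -> np.ndarray:
    """Disc detector: circular mean minus wide rectangular background mean.

    The radius-40 circular kernel matches the disc at the 540-px retina
    scale; the 80x160 rectangle samples the horizontally flanking, darker
    retina.  Negative responses are clipped — only an excess of brightness
    over the local background is disc evidence.
    """
    diff = disc_mean(i_c, circle_radius) - box_mean(i_c, rect)
    np.clip(diff, 0.0, None, out=diff)
    return diff


def locate(
    d_od: np.ndarray,
    constraint: np.ndarray | None,
    fov: FOVMask,
    scale: float = 1.0,
) -> ODCenter:
    """Constrained argmax of the disc detector.

    The maximum of ``D_OD`` over pixels inside both the vessel constraint
    mask and the FOV is the disc center estimate.  If the intersection is
    empty the argmax over the FOV alone is returned (``constrained=False``)
    so the segmentation stage always has a starting point.  Ties are broken
    by smallest row, then smallest column.
    """
    d_od = np.asarray(d_od, dtype=np.float64)
    fov_mask = np.asarray(fov.mask, dtype=bool)
    if d_od.shape != fov_mask.shape:
        raise ValueError("detector map and FOV mask must share a shape")
    if not fov_mask.any():
        raise ValueError("empty FOV mask")
    constrained = True
    valid = fov_mask
    if constraint is not None:
        both = fov_mask & np.asarray(constraint, dtype=bool)
        if both.any():
            valid = both
        else:
            constrained = False
            logger.warning("empty vessel constraint mask; falling back to FOV-wide argmax")
    else:
        constrained = False
    masked = np.where(valid, d_od, -np.inf)
    flat = int(masked.argmax())  # C-order: first occurrence = smallest row, then col
    row, col = divmod(flat, d_od.shape[1])
    return ODCenter(
        row_norm=int(row),
        col_norm=int(col),
        row_orig=row / scale,
        col_orig=col / scale,
        detector_value=float(d_od[row, col]),
        constrained=constrained,
    )
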