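"""Averaging filters shared by the vessel-density and disc-detector stages.

Both detector maps are differences of local means: a narrow kernel that
matches the scale of the structure of interest (vessel bundle, disc) minus a
wide kernel that samples the surrounding background.  All means use reflect
("symmetric") padding so the FOV rim does not produce spurious maxima.

Window conventions
------------------
For an even kernel extent ``k`` the window spans offsets ``-(k//2) .. k//2-1``
around the output pixel (the scipy ``uniform_filter`` convention); odd extents
are symmetric.  The circular mean uses the radius-``r`` disc footprint
(pixels at Euclidean distance <= r from the center).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk


def box_mean(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Mean over a ``rows x cols`` rectangular window, reflect padding.

    Parameters
    ----------
    image : 2-D array
    size : (rows, cols) window extents, positive integers.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("box_mean expects a 2-D raster")
    kr, kc = int(size[0]), int(size[1])
    if kr < 1 or kc < 1:
        raise ValueError("kernel extents must be positive")
    return ndi.uniform_filter(image, size=(kr, kc), mode="reflect")


def disc_footprint(radius: int) -> np.ndarray:
    """Boolean disc footprint of the given integer radius (d <= radius)."""
    return disk(int(radius)).astype(bool)


def disc_mean(image: np.ndarray, radius: int) -> np.ndarray:
    """Mean over the radius-``radius`` disc footprint, reflect padding.

    Computed exactly (no FFT) by summing per-row runs of the disc on a
    symmetrically padded integral image, so results agree with a direct
    windowed sum to floating-point round-off.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("disc_mean expects a 2-D raster")
    r = int(radius)
    if r < 0:
        raise ValueError("radius must be nonnegative")
    if r == 0:
        return image.copy()
    h, w = image.shape
    padded = np.pad(image, r, mode="symmetric")
    # cumulative row sums with a zero column prepended: csum[y, x+1]-csum[y, x0]
    csum = np.zeros((h + 2 * r, w + 2 * r + 1), dtype=np.float64)
    np.cumsum(padded, axis=1, out=csum[:, 1:])
    # per-row half-widths of the disc footprint
    dy = np.arange(-r, r + 1)
    half = np.floor(np.sqrt(float(r) ** 2 - dy.astype(np.float64) ** 2)).astype(int)
    total = np.zeros((h, w), dtype=np.float64)
    area = 0
    for off, hw in zip(dy, half):
        rows = slice(r + off, r + off + h)
        total += csum[rows, r + hw + 1 : r + hw + 1 + w] - csum[rows, r - hw : r - hw + w]
        area += 2 * hw + 1
    return total / float(area)
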