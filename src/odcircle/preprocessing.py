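"""Field-of-view detection, retina-diameter normalization, channel helpers.

A fundus photograph shows a circular retinal field of view (FOV) on a dark
surround.  The FOV diameter defines the "retina diameter"; the whole pipeline
operates on images rescaled with cubic interpolation so that this diameter
equals 540 pixels, which makes every downstream kernel size
resolution-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize


class FOVNotFoundError(ValueError):
    """Raised when no plausible circular field of view is detected."""


@dataclass
class FOVMask:
    """Detected circular field of view.

    Attributes
    ----------
    mask : boolean raster, the single connected FOV component (hole-filled).
    diameter_px : larger axis of the mask bounding box, in pixels.
    center : (row, col) centroid of the mask.
    """

    mask: np.ndarray
    diameter_px: float
    center: tuple[float, float]


@dataclass
class WorkingImage:
    """An RGB fundus image in the normalized 540-px-retina-diameter frame.

    ``scale`` is the factor from original to normalized pixels
    (540 / original retina diameter); ``fov`` is re-detected on the
    resized image.
    """

    rgb: np.ndarray
    fov: FOVMask
    scale: float
    original_shape: tuple[int, int]


# minimum fraction of the frame the FOV must cover
_MIN_FOV_FRACTION = 0.10
# binarization threshold as a fraction of the summed-channel maximum
_FOV_THRESHOLD_FRACTION = 0.10

_STRUCTURE_4 = ndi.generate_binary_structure(2, 1)


def load_image(path) -> np.ndarray:
    """Read an RGB raster (PNG/JPEG/TIFF); first three channels are R, G, B.

    Non-8-bit inputs are linearly rescaled to 8-bit with a warning.
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] < 3:
        raise ValueError(f"expected >= 3 channels, got shape {arr.shape}")
    arr = arr[..., :3]
    if arr.dtype != np.uint8:
        warnings.warn(
            f"rescaling {arr.dtype} image to 8-bit", stacklevel=2
        )
        arr = arr.astype(np.float64)
        lo, hi = arr.min(), arr.max()
        if hi > lo:
            arr = (arr - lo) / (hi - lo) * 255.0
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    return arr


def detect_fov(rgb: np.ndarray) -> FOVMask:
    """Detect the circular field of view of a fundus image.

    The summed-channel image is binarized at 10% of its maximum, the largest
    4-connected component is kept and hole-filled.  The retina diameter is
    the larger axis of the component's bounding box, which tolerates FOVs
    cropped at top and bottom as produced by many fundus cameras.

    Raises
    ------
    FOVNotFoundError
        If the candidate region covers less than 10% of the frame.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] < 3:
        raise ValueError("detect_fov expects a 3-channel raster")
    if min(rgb.shape[:2]) < 64:
        raise ValueError("image too small for FOV detection (min dim 64 px)")
    summed = rgb[..., :3].astype(np.float64).sum(axis=-1)
    peak = summed.max()
    candidate = summed > _FOV_THRESHOLD_FRACTION * peak
    if peak <= 0 or not candidate.any():
        raise FOVNotFoundError("no bright field-of-view candidate region")
    labels, n = ndi.label(candidate, structure=_STRUCTURE_4)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == sizes.argmax()
    mask = ndi.binary_fill_holes(mask, structure=_STRUCTURE_4)
    frame_area = mask.shape[0] * mask.shape[1]
    if mask.sum() < _MIN_FOV_FRACTION * frame_area:
        raise FOVNotFoundError(
            f"candidate FOV covers {mask.sum() / frame_area:.1%} of the frame (< 10%)"
        )
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    height = rows[-1] - rows[0] + 1
    width = cols[-1] - cols[0] + 1
    center = ndi.center_of_mass(mask)
    return FOVMask(mask=mask, diameter_px=float(max(height, width)), center=(float(center[0]), float(center[1])))


def normalize_scale(
    rgb: np.ndarray,
    fov: FOVMask | None = None,
    retina_diameter: int = 540,
) -> WorkingImage:
    """Resize so the retina diameter equals ``retina_diameter`` pixels.

    Uses cubic interpolation (with Gaussian pre-filtering when shrinking);
    the FOV is re-detected on the resized result.
    """
    rgb = np.asarray(rgb)
    if fov is None:
        fov = detect_fov(rgb)
    scale = retina_diameter / fov.diameter_px
    out_shape = (
        max(1, int(round(rgb.shape[0] * scale))),
        max(1, int(round(rgb.shape[1] * scale))),
    )
    resized = resize(
        rgb.astype(np.float64),
        out_shape + rgb.shape[2:],
        order=3,
        mode="edge",
        anti_aliasing=scale < 1.0,
        preserve_range=True,
    )
    resized = np.clip(np.round(resized), 0, 255).astype(np.uint8)
    new_fov = detect_fov(resized)
    return WorkingImage(
        rgb=resized,
        fov=new_fov,
        scale=float(scale),
        original_shape=(int(rgb.shape[0]), int(rgb.shape[1])),
    )


def complement_green(w: WorkingImage | np.ndarray) -> np.ndarray:
    """Complement of the green channel, ``G_c = 255 - G`` (8-bit).

    Vessels are dark in green; complementing makes them the bright
    structures that the top-hat enhancement isolates.
    """
    rgb = w.rgb if isinstance(w, WorkingImage) else np.asarray(w)
    if rgb.ndim == 3:
        green = rgb[..., 1]
    else:
        green = rgb
    return (255 - green.astype(np.uint8)).astype(np.uint8)
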