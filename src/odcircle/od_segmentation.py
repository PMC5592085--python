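"""Circle fitting by maximal ring contrast around the estimated disc center.

The intensity image is cropped to a square window centered on the estimated
disc center.  For each candidate radius ``r`` on a grid (25% to 45% of the
window side, 1% steps) the contrast measure

    CM(r) = mean intensity of the inner ring - mean intensity of the outer ring

is evaluated, where the inner ring spans distances ``[r - t, r)`` and the
outer ring ``[r, r + t)`` from the window center (ring thickness ``t`` = 4%
of the side).  The radius maximizing CM approximates the disc boundary.  The
flexible variant scans the four half-plane sectors (up/down/left/right)
independently; the final circle center is the window center shifted by half
the radius differences and the final radius is the mean of the four sector
radii.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .od_localization import ODCenter


@dataclass
class CropWindow:
    """Square intensity window around the estimated disc center.

    ``origin`` is the (row, col) of the window's top-left pixel in the
    source frame (may be negative); out-of-frame pixels were filled by edge
    replication.  ``center_local`` is the geometric window center
    ``(side/2, side/2)``.
    """

    side: int
    origin: tuple[int, int]
    intensity: np.ndarray
    center_local: tuple[float, float]


@dataclass
class SectorRadii:
    """Maximal-contrast radii of the four half-plane sectors (pixels)."""

    r_up: float
    r_down: float
    r_left: float
    r_right: float

    def as_dict(self) -> dict[str, float]:
        return {
            "up": self.r_up,
            "down": self.r_down,
            "left": self.r_left,
            "right": self.r_right,
        }


@dataclass
class CircleModel:
    """A circle in source-frame (row, col) pixel coordinates."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    def scaled(self, factor: float) -> "CircleModel":
        return CircleModel(
            center=(self.center[0] * factor, self.center[1] * factor),
            radius=self.radius * factor,
        )


_SECTORS = ("full", "up", "down", "left", "right")


def crop_window(i: np.ndarray, center: ODCenter | tuple[int, int], side: int) -> CropWindow:
    """Crop a side x side window centered on the estimated disc center.

    The window is large enough to contain the disc plus surrounding
    background; rows/cols falling outside the source are filled by edge
    replication (index clipping).
    """
    i = np.asarray(i, dtype=np.float64)
    side = int(side)
    if side % 2 != 0 or side < 32:
        raise ValueError("side must be an even integer >= 32")
    if isinstance(center, ODCenter):
        crow, ccol = center.row_norm, center.col_norm
    else:
        crow, ccol = int(center[0]), int(center[1])
    origin = (crow - side // 2, ccol - side // 2)
    rows = np.clip(np.arange(origin[0], origin[0] + side), 0, i.shape[0] - 1)
    cols = np.clip(np.arange(origin[1], origin[1] + side), 0, i.shape[1] - 1)
    window = i[np.ix_(rows, cols)]
    return CropWindow(
        side=side,
        origin=origin,
        intensity=window,
        center_local=(side / 2.0, side / 2.0),
    )


def _distance_map(win: CropWindow) -> np.ndarray:
    rr, cc = np.mgrid[0 : win.side, 0 : win.side]
    return np.hypot(rr - win.center_local[0], cc - win.center_local[1])


def _sector_mask(win: CropWindow, sector: str) -> np.ndarray:
    """Half-plane restriction; the boundary row/col belongs to down/right."""
    if sector not in _SECTORS:
        raise ValueError(f"unknown sector {sector!r}")
    rr, cc = np.mgrid[0 : win.side, 0 : win.side]
    if sector == "full":
        return np.ones((win.side, win.side), dtype=bool)
    if sector == "up":
        return rr < win.center_local[0]
    if sector == "down":
        return rr >= win.center_local[0]
    if sector == "left":
        return cc < win.center_local[1]
    return cc >= win.center_local[1]


def ring_thickness(side: int, frac: float = 0.04) -> float:
    return frac * side


def contrast_measure(
    win: CropWindow,
    r: float,
    thickness: float | None = None,
    sector: str = "full",
    _dist: np.ndarray | None = None,
) -> float:
    """Ring contrast ``CM(r)``: inner-ring mean minus outer-ring mean.

    The inner ring spans distances ``[r - t, r)`` and the outer ring
    ``[r, r + t)`` from the window center; at the disc boundary the inner
    ring lies on the bright disc and the outer on the darker background, so
    CM peaks there.
    """
    t = ring_thickness(win.side) if thickness is None else float(thickness)
    if r <= 0 or t <= 0:
        raise ValueError("radius and thickness must be positive")
    if r + t > win.side / 2.0 * np.sqrt(2.0):
        raise ValueError("outer ring does not fit inside the window")
    d = _distance_map(win) if _dist is None else _dist
    region = _sector_mask(win, sector)
    inner = (d >= r - t) & (d < r) & region
    outer = (d >= r) & (d < r + t) & region
    if not inner.any() or not outer.any():
        raise ValueError(f"empty ring set for r={r}, thickness={t}")
    return float(win.intensity[inner].mean() - win.intensity[outer].mean())


def scan_radii(
    win: CropWindow,
    sector: str = "full",
    config: PipelineConfig | None = None,
) -> tuple[float, float]:
    """Maximal-contrast radius over the scanned grid for one sector.

    Evaluates CM on the grid ``{25%, 26%, ..., 45%} x side``; ties are broken
    toward the smallest radius.  Returns ``(radius, cm_max)``.
    """
    cfg = config or PipelineConfig()
    grid = cfg.radius_grid(win.side)
    t = ring_thickness(win.side, cfg.ring_thickness_frac)
    d = _distance_map(win)
    best_r, best_cm = None, -np.inf
    for r in grid:
        cm = contrast_measure(win, float(r), t, sector, _dist=d)
        if cm > best_cm:
            best_r, best_cm = float(r), cm
    return best_r, best_cm


def fit_rigid_circle(
    win: CropWindow, config: PipelineConfig | None = None
) -> CircleModel:
    """Single maximal-contrast circle centered on the window center."""
    r, _ = scan_radii(win, "full", config)
    return CircleModel(
        center=(win.origin[0] + win.center_local[0], win.origin[1] + win.center_local[1]),
        radius=r,
    )


def fit_flexible_circle(
    win: CropWindow, config: PipelineConfig | None = None
) -> tuple[CircleModel, SectorRadii]:
    """Four-sector flexible circle fit.

    Each half-plane sector gets its own maximal-contrast radius; the final
    center is the window center shifted by half the down-up and right-left
    radius differences and the final radius is the mean of the four.  When
    the four radii agree this degenerates exactly to the rigid fit.
    """
    cfg = config or PipelineConfig()
    r_up, _ = scan_radii(win, "up", cfg)
    r_down, _ = scan_radii(win, "down", cfg)
    r_left, _ = scan_radii(win, "left", cfg)
    r_right, _ = scan_radii(win, "right", cfg)
    radii = SectorRadii(r_up=r_up, r_down=r_down, r_left=r_left, r_right=r_right)
    row_local = win.center_local[0] + (r_down - r_up) / 2.0
    col_local = win.center_local[1] + (r_right - r_left) / 2.0
    circle = CircleModel(
        center=(win.origin[0] + row_local, win.origin[1] + col_local),
        radius=(r_up + r_down + r_left + r_right) / 4.0,
    )
    return circle, radii


def fit_disc(
    i: np.ndarray,
    center: ODCenter | tuple[int, int],
    config: PipelineConfig | None = None,
) -> tuple[CircleModel, SectorRadii, CropWindow]:
    """Flexible circle fit with iterative window re-centering.

    A single four-sector pass under-corrects a center offset: each
    semicircular ring integrates the offset boundary over its whole arc, so
    the sector radius moves by less than the offset itself.  Re-cropping the
    window at the refined center and repeating the fit converges to the
    symmetric fixed point within the radius-grid resolution in two to three
    passes; the loop stops early once the rounded center is stable.
    """
    cfg = config or PipelineConfig()
    if isinstance(center, ODCenter):
        current = (center.row_norm, center.col_norm)
    else:
        current = (int(center[0]), int(center[1]))
    win = circle = radii = None
    for _ in range(max(1, cfg.refine_passes)):
        win = crop_window(i, current, cfg.crop_side)
        circle, radii = fit_flexible_circle(win, cfg)
        refined = (int(round(circle.center[0])), int(round(circle.center[1])))
        if refined == current:
            break
        current = refined
    return circle, radii, win


def rasterize_circle(c: CircleModel, shape: tuple[int, int]) -> np.ndarray:
    """Binary mask of pixels whose centers lie within the circle."""
    rows, cols = int(shape[0]), int(shape[1])
    if rows <= 0 or cols <= 0:
        raise ValueError("shape must be positive")
    rr, cc = np.mgrid[0:rows, 0:cols]
    return np.hypot(rr - c.center[0], cc - c.center[1]) <= c.radius
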