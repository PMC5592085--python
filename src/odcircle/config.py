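"""Pipeline configuration: every tunable constant of the method in one place.

Defaults are the published operating point for images normalized to a
540-pixel retina diameter; they only need revisiting for a different capture
angle.  Kernel sizes are (rows, cols).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np


@dataclass
class PipelineConfig:
    """Parameters of the localization and segmentation pipeline.

    Attributes
    ----------
    retina_diameter : target retina diameter in pixels after rescaling.
    tophat_radius : radius of the disc structuring element of the white
        top-hat used for vessel enhancement.
    density_kernel_narrow, density_kernel_wide : (rows, cols) extents of the
        two averaging filters whose difference is the vessel-density map.
    density_threshold, convergence_threshold : thresholds applied to the
        max-normalized density / convergence maps (strict ``>``).
    convergence_avg_radius : radius of the circular averaging filter applied
        to the Hough line-intersection accumulator.
    hough_top_k : number of Hough line peaks retained.
    hough_min_distance, hough_min_angle_deg : minimum separation between
        retained accumulator peaks (pixels of rho, degrees of theta).
    hough_peak_floor : accumulator peaks below this fraction of the
        accumulator maximum are discarded even when fewer than
        ``hough_top_k`` peaks were found, so isolated straight structures do
        not spawn spurious low-vote lines.
    intersection_min_angle_deg : line pairs meeting at less than this angle
        are skipped (near-parallel, numerically unstable intersections).
    canny_sigma : Gaussian scale of the Canny edge detector.
    canny_low_pct, canny_high_pct : hysteresis thresholds as percentiles of
        the gradient-magnitude distribution inside the FOV.
    vessel_percentile : percentile of the enhanced-vessel map above which
        pixels are painted with max intensity before disc detection.
    detector_circle_radius : radius of the circular mean of the disc detector.
    detector_rect : (rows, cols) extents of the wide background mean of the
        disc detector.
    crop_side : side length (pixels, even) of the segmentation crop window
        in the normalized frame.
    radius_grid_min, radius_grid_max, radius_grid_step : scanned radius grid
        as fractions of the crop side.
    ring_thickness_frac : ring thickness as a fraction of the crop side.
    refine_passes : maximum number of crop-and-fit passes of the flexible
        circle fit; the window is re-centered on the refined estimate
        between passes (stops early once stable).
    """

    retina_diameter: int = 540
    tophat_radius: int = 8
    density_kernel_narrow: tuple[int, int] = (80, 40)
    density_kernel_wide: tuple[int, int] = (80, 120)
    density_threshold: float = 0.3
    convergence_threshold: float = 0.3
    convergence_avg_radius: int = 40
    hough_top_k: int = 30
    hough_min_distance: int = 5
    hough_min_angle_deg: int = 5
    hough_peak_floor: float = 0.2
    intersection_min_angle_deg: float = 3.0
    canny_sigma: float = 1.0
    canny_low_pct: float = 70.0
    canny_high_pct: float = 90.0
    vessel_percentile: float = 98.5
    detector_circle_radius: int = 40
    detector_rect: tuple[int, int] = (80, 160)
    crop_side: int = 160
    radius_grid_min: float = 0.25
    radius_grid_max: float = 0.45
    radius_grid_step: float = 0.01
    ring_thickness_frac: float = 0.04
    refine_passes: int = 3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("density_threshold", "convergence_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "retina_diameter",
            "tophat_radius",
            "convergence_avg_radius",
            "hough_top_k",
            "detector_circle_radius",
            "crop_side",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("density_kernel_narrow", "density_kernel_wide", "detector_rect"):
            kr, kc = getattr(self, name)
            if kr <= 0 or kc <= 0:
                raise ValueError(f"{name} extents must be positive")
        if self.crop_side % 2 != 0:
            raise ValueError("crop_side must be even")
        if not self.radius_grid_min < self.radius_grid_max:
            raise ValueError("radius grid min must be below max")
        if self.radius_grid_step <= 0 or self.ring_thickness_frac <= 0:
            raise ValueError("grid step and ring thickness must be positive")
        if self.refine_passes < 1:
            raise ValueError("refine_passes must be >= 1")
        if not 0.0 < self.vessel_percentile < 100.0:
            raise ValueError("vessel_percentile must lie in (0, 100)")

    # -- flat key=value serialization ------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        lines = []
        for field in dataclasses.fields(self):
            value = getattr(self, field.name)
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            lines.append(f"{field.name} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        values = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, _, text = line.partition("=")
            values[key.strip()] = text.strip()
        return cls.from_strings(values)

    @classmethod
    def from_strings(cls, values: dict[str, str]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for key, text in values.items():
            if key not in fields:
                raise ValueError(f"unknown config key: {key}")
            default = getattr(cls, key)
            if isinstance(default, tuple):
                kwargs[key] = tuple(int(v) for v in text.split(","))
            elif isinstance(default, bool):
                kwargs[key] = text.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(text)
            else:
                kwargs[key] = float(text)
        return cls(**kwargs)

    def radius_grid(self, side: int | None = None) -> np.ndarray:
        """Scanned radii in pixels for a crop window of the given side."""
        side = self.crop_side if side is None else side
        n = int(round((self.radius_grid_max - self.radius_grid_min) / self.radius_grid_step))
        fracs = self.radius_grid_min + self.radius_grid_step * np.arange(n + 1)
        return fracs * float(side)
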