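"""Seedable synthetic fundus images with exact optic disc ground truth.

The generator renders the appearance model the pipeline relies on: a
circular field of view on a dark surround, a reddish retinal background
with a multiplicative illumination gradient, a bright yellowish disc with a
smooth rim, dark curved vessels (darker in the green channel) converging on
the disc center and extending to the FOV rim, optional bright exudate
blobs away from the disc, and additive Gaussian sensor noise.  The ground
truth is the exact rasterized disc before noise.

It is deliberately not photorealistic — no peripapillary atrophy,
haemorrhages or camera color models — but it reproduces every cue the
method exploits, with known geometry, so localization and segmentation
accuracy can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .metrics import GroundTruth
from .od_segmentation import CircleModel, rasterize_circle


@dataclass
class SyntheticSpec:
    """Full description of one synthetic fundus image.

    Intensities are 8-bit per-channel means; lengths are pixels of the
    generated frame.  The disc must lie fully inside the FOV.
    """

    frame: tuple[int, int] = (600, 620)
    fov_radius: float = 270.0
    disc_center: tuple[float, float] = (280.0, 400.0)
    disc_radius: float = 54.0
    disc_intensity: tuple[float, float, float] = (245.0, 215.0, 135.0)
    background_intensity: tuple[float, float, float] = (175.0, 95.0, 55.0)
    rim_softness: float = 2.0
    n_vessels: int = 9
    vessel_width: float = 4.0
    vessel_darkness: float = 0.55
    n_exudates: int = 0
    illumination_gradient: float = 0.15
    noise_sigma: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        fc = (self.frame[0] / 2.0, self.frame[1] / 2.0)
        off = float(np.hypot(self.disc_center[0] - fc[0], self.disc_center[1] - fc[1]))
        if off + self.disc_radius >= self.fov_radius:
            raise ValueError("disc must lie fully inside the FOV")
        for name in ("disc_intensity", "background_intensity"):
            if any(not 0 <= v <= 255 for v in getattr(self, name)):
                raise ValueError(f"{name} channels must lie in [0, 255]")
        if self.noise_sigma < 0 or self.vessel_width <= 0:
            raise ValueError("noise_sigma must be >= 0 and vessel_width > 0")
        if not 0.0 <= self.vessel_darkness <= 1.0:
            raise ValueError("vessel_darkness must lie in [0, 1]")


def _quadratic_bezier(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, p1, p2 = (np.asarray(p, dtype=np.float64) for p in (p0, p1, p2))
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _vessel_polylines(spec: SyntheticSpec, rng: np.random.Generator) -> list[np.ndarray]:
    """Quadratic vessel splines from the FOV rim to near the disc center."""
    fc = np.array([spec.frame[0] / 2.0, spec.frame[1] / 2.0])
    polylines = []
    for _ in range(spec.n_vessels):
        angle = rng.uniform(0.0, 2.0 * np.pi)
        start = fc + 0.97 * spec.fov_radius * np.array([np.sin(angle), np.cos(angle)])
        # endpoint within 0.2 disc radii of the disc center
        end_angle = rng.uniform(0.0, 2.0 * np.pi)
        end_off = rng.uniform(0.0, 0.2 * spec.disc_radius)
        end = np.array(spec.disc_center) + end_off * np.array(
            [np.sin(end_angle), np.cos(end_angle)]
        )
        chord = end - start
        normal = np.array([-chord[1], chord[0]])
        norm = np.linalg.norm(normal)
        normal = normal / norm if norm > 0 else normal
        bend = rng.uniform(-0.25, 0.25) * np.linalg.norm(chord)
        control = (start + end) / 2.0 + bend * normal
        n_samples = max(16, int(np.linalg.norm(chord) * 2))
        poly = _quadratic_bezier(start, control, end, n_samples)
        assert np.hypot(*(poly[-1] - np.array(spec.disc_center))) <= 0.2 * spec.disc_radius
        polylines.append(poly)
    return polylines


def generate(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic fundus image and its exact ground-truth mask."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.frame
    fc = (rows / 2.0, cols / 2.0)
    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)
    d_fov = np.hypot(rr - fc[0], cc - fc[1])
    fov_mask = d_fov <= spec.fov_radius

    img = np.empty((rows, cols, 3), dtype=np.float64)
    for ch in range(3):
        img[..., ch] = spec.background_intensity[ch]

    # multiplicative illumination ramp across the FOV, random direction
    phi = rng.uniform(0.0, 2.0 * np.pi)
    ramp = ((rr - fc[0]) * np.sin(phi) + (cc - fc[1]) * np.cos(phi)) / spec.fov_radius
    illum = 1.0 + 0.5 * spec.illumination_gradient * ramp
    img *= illum[..., None]

    # bright disc with sigmoidal rim profile
    d_disc = np.hypot(rr - spec.disc_center[0], cc - spec.disc_center[1])
    softness = max(spec.rim_softness, 1e-6)
    w_disc = 1.0 / (1.0 + np.exp((d_disc - spec.disc_radius) / softness))
    for ch in range(3):
        img[..., ch] = img[..., ch] * (1 - w_disc) + spec.disc_intensity[ch] * w_disc

    # dark vessels: polyline stamps dilated to width, anti-aliased, deepest in green
    canvas = np.zeros((rows, cols), dtype=bool)
    for poly in _vessel_polylines(spec, rng):
        pr = np.clip(np.round(poly[:, 0]).astype(int), 0, rows - 1)
        pc = np.clip(np.round(poly[:, 1]).astype(int), 0, cols - 1)
        canvas[pr, pc] = True
    half_width = max(int(round(spec.vessel_width / 2.0)), 1)
    yy, xx = np.mgrid[-half_width : half_width + 1, -half_width : half_width + 1]
    canvas = ndi.binary_dilation(canvas, structure=np.hypot(yy, xx) <= half_width)
    vessel_profile = ndi.gaussian_filter(canvas.astype(np.float64), 0.8)
    vessel_profile = np.clip(vessel_profile, 0.0, 1.0)
    channel_weight = (0.75, 1.0, 0.6)  # green darkest, best vessel contrast
    for ch in range(3):
        img[..., ch] *= 1.0 - spec.vessel_darkness * channel_weight[ch] * vessel_profile

    # bright exudate blobs at >= 2 disc radii from the disc center
    for _ in range(spec.n_exudates):
        for _attempt in range(100):
            er = rng.uniform(0.0, 0.85 * spec.fov_radius)
            ea = rng.uniform(0.0, 2.0 * np.pi)
            pos = (fc[0] + er * np.sin(ea), fc[1] + er * np.cos(ea))
            if np.hypot(pos[0] - spec.disc_center[0], pos[1] - spec.disc_center[1]) >= 2.0 * spec.disc_radius:
                break
        blob_r = rng.uniform(3.0, 8.0)
        blob = np.exp(-0.5 * (np.hypot(rr - pos[0], cc - pos[1]) / blob_r) ** 2)
        for ch in range(3):
            img[..., ch] = img[..., ch] * (1 - blob) + spec.disc_intensity[ch] * blob

    # dark surround outside the FOV
    img[~fov_mask] = 2.0

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    rgb = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth_mask = rasterize_circle(
        CircleModel(center=spec.disc_center, radius=spec.disc_radius), (rows, cols)
    )
    return rgb, GroundTruth.from_mask(truth_mask)


def default_battery_specs(n: int, master_seed: int) -> list[SyntheticSpec]:
    """Randomized image specs emulating a small screening-set's variety.

    Disc anywhere in the nasal half of the FOV (either laterality), disc
    radius 8-12% of the FOV diameter, 6-12 vessels, sensor noise sigma 4-8;
    fully determined by ``master_seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(master_seed)
    specs = []
    for _ in range(n):
        fov_radius = float(rng.uniform(240.0, 300.0))
        margin = int(rng.integers(10, 30))
        frame = (2 * int(fov_radius) + 2 * margin, 2 * int(fov_radius) + 2 * margin + int(rng.integers(0, 40)))
        fc = (frame[0] / 2.0, frame[1] / 2.0)
        disc_radius = float(rng.uniform(0.08, 0.12) * 2.0 * fov_radius)
        side = rng.choice([-1.0, 1.0])  # laterality: nasal side left or right
        dx = side * rng.uniform(0.25, 0.55) * fov_radius
        dy = rng.uniform(-0.20, 0.20) * fov_radius
        disc_center = (fc[0] + dy, fc[1] + dx)
        specs.append(
            SyntheticSpec(
                frame=frame,
                fov_radius=fov_radius,
                disc_center=disc_center,
                disc_radius=disc_radius,
                disc_intensity=tuple(
                    float(np.clip(v + rng.normal(0.0, 6.0), 0, 255))
                    for v in (243.0, 214.0, 135.0)
                ),
                background_intensity=tuple(
                    float(np.clip(v + rng.normal(0.0, 10.0), 0, 255))
                    for v in (175.0, 95.0, 55.0)
                ),
                rim_softness=float(rng.uniform(1.5, 3.0)),
                n_vessels=int(rng.integers(6, 13)),
                vessel_width=float(rng.uniform(3.0, 5.0)),
                vessel_darkness=float(rng.uniform(0.45, 0.65)),
                n_exudates=int(rng.integers(0, 3)),
                illumination_gradient=float(rng.uniform(0.0, 0.25)),
                noise_sigma=float(rng.uniform(4.0, 8.0)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def default_battery(n: int, master_seed: int) -> list[tuple[np.ndarray, GroundTruth]]:
    """Generate the default battery of ``n`` images with ground truth."""
    return [generate(spec) for spec in default_battery_specs(n, master_seed)]
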