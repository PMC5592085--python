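"""Crop window, ring-contrast measure, radius scans and circle fitting."""

import numpy as np
import pytest

from conftest import disc_image
from odcircle.config import PipelineConfig
from odcircle.od_segmentation import (
    CircleModel,
    CropWindow,
    contrast_measure,
    crop_window,
    fit_disc,
    fit_flexible_circle,
    fit_rigid_circle,
    rasterize_circle,
    scan_radii,
)

SIDE = 160
GRID_STEP = 0.01 * SIDE


def make_window(intensity: np.ndarray) -> CropWindow:
    side = intensity.shape[0]
    return CropWindow(
        side=side, origin=(0, 0), intensity=intensity.astype(np.float64),
        center_local=(side / 2.0, side / 2.0),
    )


def disc_window(radius, offset=(0.0, 0.0), disc=300.0, background=100.0, side=SIDE):
    center = (side / 2.0 + offset[0], side / 2.0 + offset[1])
    return make_window(disc_image((side, side), center, radius, disc, background))


class TestCropWindow:
    def test_interior_crop_is_exact(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 765, size=(400, 400))
        win = crop_window(img, (200, 210), 140)
        assert win.origin == (130, 140)
        np.testing.assert_array_equal(win.intensity, img[130:270, 140:280])
        assert win.center_local == (70.0, 70.0)

    def test_edge_replication_near_top(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 765, size=(400, 400))
        win = crop_window(img, (10, 200), 140)
        # the first 60 window rows replicate source row 0
        for r in range(60):
            np.testing.assert_array_equal(win.intensity[r], img[0, 130:270])
        np.testing.assert_array_equal(win.intensity[60], img[0 + 0, 130:270])
        np.testing.assert_array_equal(win.intensity[61], img[1, 130:270])

    def test_rejects_odd_or_small_side(self):
        img = np.zeros((100, 100))
        with pytest.raises(ValueError):
            crop_window(img, (50, 50), 141)
        with pytest.raises(ValueError):
            crop_window(img, (50, 50), 30)


class TestContrastMeasure:
    def test_ideal_disc_boundary_gives_unit_contrast(self):
        # ring at the exact boundary: inner fully on the disc, outer fully off
        win = disc_window(radius=56.2, disc=1.0, background=0.0)
        assert contrast_measure(win, 56.2) == pytest.approx(1.0)

    def test_rings_inside_disc_give_zero(self):
        win = disc_window(radius=70.0, disc=1.0, background=0.0)
        assert contrast_measure(win, 45.0) == pytest.approx(0.0)

    def test_additive_invariance_and_multiplicative_scaling(self):
        rng = np.random.default_rng(9)
        win = make_window(rng.uniform(0, 765, size=(SIDE, SIDE)))
        base = contrast_measure(win, 50.0)
        shifted = make_window(win.intensity + 123.456)
        scaled = make_window(win.intensity * 2.5)
        assert contrast_measure(shifted, 50.0) == pytest.approx(base, abs=1e-9)
        assert contrast_measure(scaled, 50.0) == pytest.approx(2.5 * base, abs=1e-9)

    def test_oversized_radius_is_an_error(self):
        win = disc_window(radius=40.0)
        with pytest.raises(ValueError):
            contrast_measure(win, 160.0)


class TestScanRadii:
    def test_recovers_centered_disc_radius(self):
        r0 = 0.35 * SIDE
        win = disc_window(radius=r0)
        r, cm = scan_radii(win, "full")
        assert abs(r - r0) <= GRID_STEP
        assert cm > 0

    def test_sectors_agree_on_symmetric_disc(self):
        win = disc_window(radius=0.35 * SIDE)
        r_full, _ = scan_radii(win, "full")
        for sector in ("up", "down", "left", "right"):
            r_sec, _ = scan_radii(win, sector)
            assert r_sec == pytest.approx(r_full)

    def test_uniform_window_returns_smallest_radius(self):
        win = make_window(np.full((SIDE, SIDE), 42.0))
        cfg = PipelineConfig()
        r, cm = scan_radii(win, "full", cfg)
        assert r == pytest.approx(cfg.radius_grid(SIDE)[0])
        assert cm == pytest.approx(0.0)

    def test_unknown_sector_rejected(self):
        with pytest.raises(ValueError):
            scan_radii(disc_window(radius=50.0), "diagonal")


class TestFlexibleFit:
    def test_centered_disc_matches_rigid_fit(self):
        win = disc_window(radius=0.35 * SIDE)
        rigid = fit_rigid_circle(win)
        flexible, radii = fit_flexible_circle(win)
        assert flexible.center == rigid.center
        assert flexible.radius == pytest.approx(rigid.radius)
        assert radii.r_up == radii.r_down == radii.r_left == radii.r_right

    def test_shifted_disc_single_pass_moves_toward_center(self):
        # A semicircular ring integrates the offset boundary over its whole
        # arc, so one pass responds to a +5 px column offset with
        # r_right - r_left somewhere between 0 and 10 px: the center moves
        # toward the truth without overshooting, and the radius is unbiased.
        r0 = 50.0
        win = disc_window(radius=r0, offset=(0.0, 5.0))
        circle, radii = fit_flexible_circle(win)
        assert radii.r_right > radii.r_left
        assert radii.r_right - radii.r_left <= 10.0 + GRID_STEP
        shift = circle.center[1] - SIDE / 2.0
        assert 0.0 < shift <= 5.0 + GRID_STEP
        assert abs(circle.center[0] - SIDE / 2.0) <= GRID_STEP
        assert circle.radius == pytest.approx(r0, abs=GRID_STEP)

    def test_shifted_disc_iterative_fit_recovers_center(self):
        r0 = 50.0
        offset = (4.0, 5.0)
        source = disc_image(
            (2 * SIDE, 2 * SIDE),
            (SIDE + offset[0], SIDE + offset[1]),
            r0, 300.0, 100.0,
        )
        circle, radii, _ = fit_disc(source, (SIDE, SIDE))
        assert abs(circle.center[0] - (SIDE + offset[0])) <= GRID_STEP
        assert abs(circle.center[1] - (SIDE + offset[1])) <= GRID_STEP
        assert circle.radius == pytest.approx(r0, abs=GRID_STEP)

    def test_origin_maps_center_to_source_frame(self):
        win = disc_window(radius=0.35 * SIDE)
        win_shifted = CropWindow(
            side=win.side, origin=(100, 250), intensity=win.intensity,
            center_local=win.center_local,
        )
        circle, _ = fit_flexible_circle(win_shifted)
        assert circle.center == (100 + SIDE / 2.0, 250 + SIDE / 2.0)


class TestRasterizeCircle:
    def test_subpixel_radius_hits_single_pixel(self):
        mask = rasterize_circle(CircleModel(center=(5.0, 7.0), radius=0.4), (12, 12))
        assert mask.sum() == 1 and mask[5, 7]

    def test_area_matches_continuous_circle(self):
        mask = rasterize_circle(CircleModel(center=(100.0, 100.0), radius=50.0), (200, 200))
        assert abs(int(mask.sum()) - np.pi * 50**2) <= 0.01 * np.pi * 50**2

    def test_reflection_symmetry_about_pixel_center(self):
        mask = rasterize_circle(CircleModel(center=(20.0, 20.0), radius=7.3), (41, 41))
        np.testing.assert_array_equal(mask, mask[::-1, :])
        np.testing.assert_array_equal(mask, mask[:, ::-1])

    def test_rejects_nonpositive_radius_or_shape(self):
        with pytest.raises(ValueError):
            CircleModel(center=(0, 0), radius=0.0)
        with pytest.raises(ValueError):
            rasterize_circle(CircleModel(center=(0, 0), radius=1.0), (0, 5))
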