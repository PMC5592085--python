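"""Vessel enhancement, density, convergence and mask combination."""

import numpy as np
import pytest

from odcircle.filters import disc_footprint
from odcircle.vessel_evidence import (
    binarize_normalized,
    combine_masks,
    enhance_vessels,
    line_pair_intersections,
    vessel_convergence,
    vessel_density,
)


def brute_tophat(image: np.ndarray, radius: int) -> np.ndarray:
    """Independent top-hat: min then max over the disc footprint, each with
    symmetric padding, subtracted from the input."""
    fp = disc_footprint(radius)
    offsets = np.argwhere(fp) - radius

    def slide(img, reduce_fn):
        padded = np.pad(img, radius, mode="symmetric")
        h, w = img.shape
        stack = np.stack(
            [padded[radius + dr : radius + dr + h, radius + dc : radius + dc + w] for dr, dc in offsets]
        )
        return reduce_fn(stack, axis=0)

    opened = slide(slide(image, np.min), np.max)
    return image - opened


class TestEnhanceVessels:
    def test_constant_image_gives_zero(self):
        np.testing.assert_array_equal(enhance_vessels(np.full((40, 40), 77.0)), 0.0)

    def test_isolated_peak_survives_fully(self):
        img = np.zeros((40, 40))
        img[20, 20] = 100.0
        out = enhance_vessels(img)
        assert out[20, 20] == 100.0
        out[20, 20] = 0.0
        np.testing.assert_array_equal(out, 0.0)

    def test_large_square_interior_is_removed(self):
        img = np.zeros((100, 100))
        img[25:75, 25:75] = 100.0
        out = enhance_vessels(img, radius=8)
        # the radius-8 disc fits inside: no response >= 8 px from the edge
        np.testing.assert_array_equal(out[33:67, 33:67], 0.0)

    def test_offset_invariance(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 200, size=(50, 60)).astype(np.float64)
        np.testing.assert_array_equal(enhance_vessels(img + 17.0), enhance_vessels(img))

    @pytest.mark.parametrize("radius", [2, 4])
    def test_matches_brute_force_morphology(self, radius):
        rng = np.random.default_rng(13)
        for _ in range(5):
            img = rng.uniform(0, 255, size=rng.integers(16, 48, size=2))
            np.testing.assert_allclose(
                enhance_vessels(img, radius), brute_tophat(img, radius), atol=1e-9
            )


class TestVesselDensity:
    def test_zero_input_yields_zero_without_warning(self):
        out = vessel_density(np.zeros((200, 200)))
        np.testing.assert_array_equal(out, 0.0)

    def test_constant_input_yields_zero_map(self):
        # equal means under reflect padding everywhere -> zero difference
        np.testing.assert_allclose(vessel_density(np.full((200, 200), 5.0)), 0.0, atol=1e-12)

    def test_vertical_strip_normalizes_to_one_at_center(self):
        img = np.zeros((300, 200))
        img[:, 90:110] = 1.0  # 20-px-wide strip
        out = vessel_density(img)
        # narrow mean 20/40, wide mean 20/120: the raw peak 1/3 maps to 1.0
        assert out[150, 100] == pytest.approx(1.0, abs=1e-9)
        assert 0.0 <= out.min() and out.max() <= 1.0

    def test_output_range_on_random_input(self):
        rng = np.random.default_rng(2)
        out = vessel_density(rng.uniform(0, 50, size=(150, 150)))
        assert out.min() >= 0.0 and out.max() == pytest.approx(1.0)


class TestVesselConvergence:
    def _strips(self, vertical_at=None, horizontal_at=None, shape=(300, 300)):
        img = np.zeros(shape)
        for c in vertical_at or []:
            img[:, c : c + 10] = 200.0
        for r in horizontal_at or []:
            img[r : r + 10, :] = 200.0
        return img

    def test_crossing_strips_peak_near_intersection(self):
        img = self._strips(vertical_at=[95], horizontal_at=[115])
        out = vessel_convergence(img)
        assert out.max() == pytest.approx(1.0)
        peak = np.unravel_index(np.argmax(out), out.shape)
        # strips cross around (119.5, 99.5)
        assert np.hypot(peak[0] - 119.5, peak[1] - 99.5) <= 40
        # independent check: the two edge-line families intersect inside
        # the crossing square, so raw intersections must exist there
        assert out[120, 100] > 0

    def test_single_strip_has_no_intersections(self):
        np.testing.assert_array_equal(vessel_convergence(self._strips(vertical_at=[95])), 0.0)

    def test_parallel_strips_have_no_intersections(self):
        out = vessel_convergence(self._strips(vertical_at=[60, 200]))
        np.testing.assert_array_equal(out, 0.0)

    def test_blank_input_yields_zero(self):
        np.testing.assert_array_equal(vessel_convergence(np.zeros((100, 100))), 0.0)


class TestLinePairIntersections:
    @staticmethod
    def oracle(lines, shape, min_angle_deg=3.0):
        """Homogeneous-coordinates cross-product oracle."""
        acc = np.zeros(shape)
        for i in range(len(lines)):
            for j in range(i + 1, len(lines)):
                t1, r1 = lines[i]
                t2, r2 = lines[j]
                delta = abs(t1 - t2) % np.pi
                if min(delta, np.pi - delta) < np.deg2rad(min_angle_deg):
                    continue
                l1 = np.array([np.cos(t1), np.sin(t1), -r1])
                l2 = np.array([np.cos(t2), np.sin(t2), -r2])
                x, y, w = np.cross(l1, l2)
                col, row = x / w, y / w
                ri, ci = int(round(row)), int(round(col))
                if 0 <= ri < shape[0] and 0 <= ci < shape[1]:
                    acc[ri, ci] += 1.0
        return acc

    def test_matches_cross_product_oracle_on_random_lines(self):
        rng = np.random.default_rng(17)
        shape = (64, 64)
        for _ in range(20):
            n = rng.integers(2, 12)
            lines = [
                (rng.uniform(-np.pi / 2, np.pi / 2), rng.uniform(-40, 80)) for _ in range(n)
            ]
            np.testing.assert_array_equal(
                line_pair_intersections(lines, shape), self.oracle(lines, shape)
            )

    def test_near_parallel_pairs_are_skipped(self):
        lines = [(0.0, 10.0), (np.deg2rad(2.0), 12.0)]
        np.testing.assert_array_equal(line_pair_intersections(lines, (50, 50)), 0.0)


class TestMaskOps:
    def test_binarize_is_strict(self):
        m = np.array([[0.31, 0.30, 0.29]])
        np.testing.assert_array_equal(binarize_normalized(m, 0.3), [[True, False, False]])
        assert not binarize_normalized(np.full((3, 3), 0.2), 0.3).any()
        with pytest.raises(ValueError):
            binarize_normalized(m, 1.5)

    def test_combine_identities(self):
        rng = np.random.default_rng(23)
        m = rng.random((20, 20)) > 0.5
        empty = np.zeros((20, 20), dtype=bool)
        np.testing.assert_array_equal(combine_masks(m, m), m)
        np.testing.assert_array_equal(combine_masks(m, empty), empty)

    def test_combine_commutative_associative(self):
        rng = np.random.default_rng(29)
        a, b, c = (rng.random((15, 15)) > 0.5 for _ in range(3))
        np.testing.assert_array_equal(combine_masks(a, b), combine_masks(b, a))
        np.testing.assert_array_equal(
            combine_masks(combine_masks(a, b), c), combine_masks(a, combine_masks(b, c))
        )

    def test_combine_shape_mismatch(self):
        with pytest.raises(ValueError):
            combine_masks(np.ones((3, 3), bool), np.ones((3, 4), bool))

    def test_disc_overlap_equals_set_intersection(self):
        rr, cc = np.mgrid[0:60, 0:60]
        d1 = np.hypot(rr - 25, cc - 25) <= 15
        d2 = np.hypot(rr - 35, cc - 35) <= 15
        combined = combine_masks(d1, d2)
        set1 = {tuple(p) for p in np.argwhere(d1)}
        set2 = {tuple(p) for p in np.argwhere(d2)}
        assert {tuple(p) for p in np.argwhere(combined)} == set1 & set2
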