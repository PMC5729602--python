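"""Magnification, blood-pool segmentation and edge extraction."""

import numpy as np
import pytest
from scipy import ndimage

from lvfractal import (
    LvPhantomSpec,
    RoiSpec,
    SegmentationError,
    SegmentationParams,
    SliceImage,
    ValidationError,
    detect_edges,
    magnify,
    segment_blood_pool,
)
from lvfractal.phantom import make_lv_slice

from conftest import dice_coefficient


def _disk_slice(n=160, r=48, inner=400.0, outer=120.0):
    rr, cc = np.ogrid[:n, :n]
    d2 = (rr - n / 2) ** 2 + (cc - n / 2) ** 2
    img = np.where(d2 <= r * r, inner, outer)
    return SliceImage(img), d2 <= r * r


class TestMagnify:
    def test_constant_image_stays_constant(self):
        s = SliceImage(np.full((40, 40), 7.0))
        out = magnify(s, 4)
        assert out.shape == (160, 160)
        np.testing.assert_allclose(out.pixels, 7.0)
        assert out.pixel_spacing == (0.25, 0.25)

    def test_factor_one_is_identity(self):
        rng = np.random.default_rng(0)
        s = SliceImage(rng.uniform(0, 100, (40, 40)))
        np.testing.assert_array_equal(magnify(s, 1).pixels, s.pixels)

    def test_planar_ramp_reproduced_exactly_in_interior(self):
        # bicubic interpolation reproduces polynomials of degree <= 3;
        # oracle = direct evaluation of the plane at magnified coordinates
        r, c = np.mgrid[0:40, 0:40]
        s = SliceImage(2.0 * r + 3.0 * c)
        out = magnify(s, 4)
        rm, cm = np.mgrid[0:160, 0:160]
        expected = 2.0 * ((rm + 0.5) / 4 - 0.5) + 3.0 * ((cm + 0.5) / 4 - 0.5)
        # the cubic-spline boundary condition perturbs the ramp near the
        # edges with geometrically decaying error; stay 12 input px away
        err = np.abs(out.pixels - expected)[48:-48, 48:-48]
        assert err.max() <= 1e-6

    def test_fractional_factor_rejected(self):
        s = SliceImage(np.zeros((40, 40)))
        with pytest.raises(ValidationError):
            magnify(s, 0)


class TestSegmentBloodPool:
    def test_two_level_disk_matches_threshold_oracle(self):
        """Noise-free disk: level-set mask equals the midpoint-threshold
        oracle up to a one-pixel boundary band."""
        s, truth = _disk_slice()
        pool = segment_blood_pool(s, roi=RoiSpec(center=(80, 80), radius=70))
        oracle = s.pixels > (400 + 120) / 2.0  # midpoint threshold
        band = ndimage.binary_dilation(truth) & ~ndimage.binary_erosion(truth)
        core = ~band
        assert dice_coefficient(pool.mask & core, oracle & core) == pytest.approx(1.0)

    def test_trabeculated_noisy_slice_dice(self):
        spec = LvPhantomSpec(complexity=0.5, noise_sd=10.0, seed=5)
        sl, truth = make_lv_slice(spec, 0.4, 0.5, np.random.default_rng(5))
        pool = segment_blood_pool(magnify(sl, 4))
        truth_mag = ndimage.zoom(truth["pool"].astype(np.uint8), 4, order=0) > 0
        assert dice_coefficient(pool.mask, truth_mag) >= 0.95

    def test_dice_across_complexity_noise_grid(self, dice_grid):
        for (c, sigma), d in dice_grid.items():
            assert d >= 0.95, f"Dice {d:.3f} at complexity={c}, noise={sigma}"

    def test_constant_roi_raises_no_contrast(self):
        s = SliceImage(np.full((64, 64), 50.0))
        with pytest.raises(SegmentationError, match="no contrast"):
            segment_blood_pool(s, roi=RoiSpec(center=(32, 32), radius=20))

    def test_deterministic_for_fixed_inputs(self):
        spec = LvPhantomSpec(complexity=0.7, seed=9)
        sl, _ = make_lv_slice(spec, 0.5, 0.7, np.random.default_rng(9))
        mag = magnify(sl, 4)
        e1 = detect_edges(segment_blood_pool(mag))
        e2 = detect_edges(segment_blood_pool(mag))
        np.testing.assert_array_equal(e1.edges, e2.edges)

    def test_translation_equivariance_interior(self):
        """Integer translation of the slice translates the edge map."""
        s, _ = _disk_slice(n=200, r=40)
        dy, dx = 7, -5
        shifted = SliceImage(np.roll(np.roll(s.pixels, dy, 0), dx, 1))
        roi0 = RoiSpec(center=(100, 100), radius=60)
        roi1 = RoiSpec(center=(100 + dy, 100 + dx), radius=60)
        p = SegmentationParams(magnification=1)
        e0 = detect_edges(segment_blood_pool(s, roi=roi0, params=p)).edges
        e1 = detect_edges(segment_blood_pool(shifted, roi=roi1, params=p)).edges
        np.testing.assert_array_equal(np.roll(np.roll(e0, dy, 0), dx, 1), e1)

    def test_threshold_fallback_agrees_on_clean_disk(self):
        s, truth = _disk_slice()
        roi = RoiSpec(center=(80, 80), radius=70)
        ls = segment_blood_pool(s, roi=roi)
        th = segment_blood_pool(s, roi=roi, params=SegmentationParams(method="threshold"))
        assert dice_coefficient(ls.mask, th.mask) > 0.99


class TestDetectEdges:
    def test_square_edge_count_and_location(self):
        """Filled 50x50 square: edge pixels live on the boundary band and
        number between the thin perimeter and twice the perimeter."""
        m = np.zeros((128, 128), dtype=bool)
        m[30:80, 40:90] = True
        e = detect_edges(m)
        count = int(e.edges.sum())
        assert 4 * 50 - 4 <= count <= 2 * (4 * 50)
        # oracle: explicit boundary band of the square (1 px each side)
        band = np.zeros_like(m)
        band[29:81, 39:91] = True
        band[31:79, 41:89] = False
        assert not np.any(e.edges & ~band)

    def test_single_pixel_mask_gives_nonempty_edges(self):
        m = np.zeros((64, 64), dtype=bool)
        m[10, 10] = True
        e = detect_edges(m)
        assert e.edges.any()
        rr, cc = np.nonzero(e.edges)
        assert np.all(np.abs(rr - 10) <= 1) and np.all(np.abs(cc - 10) <= 1)

    def test_empty_and_full_masks_rejected(self):
        with pytest.raises(ValidationError):
            detect_edges(np.zeros((64, 64), dtype=bool))
        with pytest.raises(ValidationError):
            detect_edges(np.ones((64, 64), dtype=bool))

    def test_edge_sandwich_property(self):
        """Every edge pixel 8-touches both a pool and a non-pool pixel."""
        spec = LvPhantomSpec(complexity=0.8, seed=4)
        sl, _ = make_lv_slice(spec, 0.5, 0.8, np.random.default_rng(4))
        pool = segment_blood_pool(magnify(sl, 4))
        edges = detect_edges(pool).edges
        k = np.ones((3, 3), dtype=bool)
        near_pool = ndimage.binary_dilation(pool.mask, structure=k)
        near_bg = ndimage.binary_dilation(~pool.mask, structure=k)
        assert np.all(near_pool[edges])
        assert np.all(near_bg[edges])


class TestRoiSpec:
    def test_roi_must_fit_inside_image(self):
        with pytest.raises(ValidationError):
            RoiSpec(center=(10, 10), radius=20).to_mask((64, 64))

    def test_roi_minimum_area(self):
        with pytest.raises(ValidationError):
            RoiSpec(center=(32, 32), radius=3).to_mask((64, 64))
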