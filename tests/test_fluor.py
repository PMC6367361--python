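"""Periphery bands, region intensities, shape metrics and fibre statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.draw import disk as skdisk, line as skline
from skimage.transform import rotate

from mechanocyte import synthetic as syn
from mechanocyte.fluor import (
    FluorCell,
    angle_dispersion,
    cell_shape,
    circularity,
    fiber_metrics,
    periphery_band,
    region_intensity,
)


def disk_mask(shape, center, radius):
    m = np.zeros(shape, dtype=bool)
    rr, cc = skdisk(center, radius, shape=shape)
    m[rr, cc] = True
    return m


class TestPeripheryBand:
    def test_annulus_area_ratio(self):
        """10-um disk, 4-um band: ratio (10^2 - 6^2)/10^2 = 0.64."""
        mask = disk_mask((120, 120), (60, 60), 40)  # radius 10 um at 0.25 um/px
        band = periphery_band(mask, width=4.0, pixel_size=0.25)
        assert band.sum() / mask.sum() == pytest.approx(0.64, abs=0.02)

    def test_zero_width_empty(self):
        mask = disk_mask((40, 40), (20, 20), 10)
        assert not periphery_band(mask, width=0.0, pixel_size=1.0).any()

    def test_small_cell_band_is_whole_cell(self):
        mask = disk_mask((40, 40), (20, 20), 3)  # radius 3 um at 1 um/px
        band = periphery_band(mask, width=4.0, pixel_size=1.0)
        np.testing.assert_array_equal(band, mask)

    def test_band_and_interior_partition_cell(self):
        mask = disk_mask((80, 80), (40, 40), 25)
        band = periphery_band(mask, width=5.0, pixel_size=1.0)
        interior = mask & ~band
        assert not (band & interior).any()
        np.testing.assert_array_equal(band | interior, mask)


class TestRegionIntensity:
    def test_constant_region(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[:10, :10] = True
        cell = FluorCell(mask, {"actin": np.full((20, 20), 5.0)}, 1.0)
        res = region_intensity(cell, mask, "actin")
        assert res.integrated_intensity == 500.0
        assert res.median_intensity == 5.0

    def test_even_count_median_is_midpair_mean(self):
        mask = np.zeros((2, 10), dtype=bool)
        mask[0] = True
        img = np.zeros((2, 10))
        img[0, :5] = 2.0
        img[0, 5:] = 10.0
        cell = FluorCell(mask, {"actin": img}, 1.0)
        assert region_intensity(cell, mask, "actin").median_intensity == 6.0

    def test_matches_brute_force_loop(self):
        channels, masks, _ = syn.gen_fiber_image(seed=5, n_fibers=6)
        cell_mask = disk_mask(masks[0].shape, (80, 80), 60)
        cell = FluorCell(cell_mask, channels, 0.25)
        band = periphery_band(cell_mask, width=4.0, pixel_size=0.25)
        res = region_intensity(cell, band, "actin")
        total = 0.0
        for r in range(band.shape[0]):
            for c in range(band.shape[1]):
                if band[r, c]:
                    total += channels["actin"][r, c]
        assert res.integrated_intensity == pytest.approx(total)

    def test_empty_region_rejected(self):
        mask = np.ones((5, 5), dtype=bool)
        cell = FluorCell(mask, {"actin": np.ones((5, 5))}, 1.0)
        with pytest.raises(ValueError):
            region_intensity(cell, np.zeros((5, 5), dtype=bool), "actin")


class TestCellShape:
    def test_disk_metrics(self):
        mask = disk_mask((140, 140), (70, 70), 50)
        s = cell_shape(mask, pixel_size=0.2)
        assert s.max_feret == pytest.approx(20.0, rel=0.03)
        assert s.roundness == pytest.approx(1.0, abs=0.05)
        assert s.aspect_ratio == pytest.approx(1.0, abs=0.02)

    def test_ellipse_two_to_one(self):
        rr, cc = np.mgrid[:200, :300]
        mask = (((rr - 100) / 50) ** 2 + ((cc - 150) / 100) ** 2) <= 1
        s = cell_shape(mask, pixel_size=1.0)
        assert s.aspect_ratio == pytest.approx(2.0, rel=0.02)
        assert s.roundness == pytest.approx(0.5, rel=0.03)

    def test_rotation_invariance(self):
        rr, cc = np.mgrid[:200, :200]
        mask = (((rr - 100) / 30) ** 2 + ((cc - 100) / 70) ** 2) <= 1
        a = cell_shape(mask)
        b = cell_shape(rotate(mask.astype(float), 90.0, order=0) > 0.5)
        for field in ("area", "max_feret", "roundness", "aspect_ratio"):
            assert getattr(b, field) == pytest.approx(getattr(a, field), rel=0.01)

    def test_continuous_square_circularity_closed_form(self):
        """4*pi*s^2/(4s)^2 = pi/4 for any side length."""
        assert circularity(4.0, 8.0) == pytest.approx(np.pi / 4)
        assert circularity(100.0, 40.0) == pytest.approx(np.pi / 4)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            cell_shape(np.zeros((10, 10), dtype=bool))


class TestFiberMetrics:
    @staticmethod
    def _segment_mask(shape, p0, p1):
        m = np.zeros(shape, dtype=bool)
        rr, cc = skline(*p0, *p1)
        m[rr, cc] = True
        return m

    def test_horizontal_segment(self):
        m = self._segment_mask((40, 40), (20, 5), (20, 25))
        recs, n = fiber_metrics([m], np.ones((40, 40)), pixel_size=1.0)
        assert n == 1
        assert recs[0].length == pytest.approx(20.0)
        assert recs[0].feret_angle == pytest.approx(0.0, abs=1.0)

    def test_diagonal_segment_angle(self):
        m = self._segment_mask((60, 60), (40, 10), (10, 40))  # rows up, cols right: +45 deg
        recs, _ = fiber_metrics([m], np.ones((60, 60)), pixel_size=1.0)
        assert recs[0].feret_angle == pytest.approx(45.0, abs=1.0)

    def test_count_equals_inputs(self):
        channels, masks, truth = syn.gen_fiber_image(seed=2, n_fibers=9)
        recs, n = fiber_metrics(masks, channels["actin"], pixel_size=0.25)
        assert n == truth["n_fibers"] == 9

    def test_recovers_generated_orientations(self):
        channels, masks, truth = syn.gen_fiber_image(seed=3, n_fibers=10, kappa=8.0)
        recs, _ = fiber_metrics(masks, channels["actin"], pixel_size=0.25)
        for rec, true_ang in zip(recs, truth["angles_deg"] % 180.0):
            diff = abs(rec.feret_angle - true_ang) % 180.0
            assert min(diff, 180.0 - diff) < 3.0


class TestAngleDispersion:
    def test_identical_angles_zero(self):
        assert angle_dispersion([37.0, 37.0, 37.0]) == pytest.approx(0.0, abs=1e-7)

    def test_perpendicular_pair_hand_value(self):
        """{0, 90} deg raw: Rbar = sqrt(2)/2, sqrt(-2 ln Rbar) ~ 0.8326 rad."""
        expected = np.sqrt(-2.0 * np.log(np.sqrt(2.0) / 2.0))
        assert angle_dispersion([0.0, 90.0], mode="raw") == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.8326, abs=1e-4)

    def test_axial_mode_treats_orientations(self):
        """{10, 170} behaves like {10, -10} under axial doubling and is
        strictly tighter than the raw statistic on the same input."""
        axial = angle_dispersion([10.0, 170.0], mode="axial")
        assert axial == pytest.approx(angle_dispersion([10.0, -10.0], mode="axial"), abs=1e-9)
        assert axial < angle_dispersion([10.0, 170.0], mode="raw")
        assert axial < 0.4

    @given(shift=st.floats(-720, 720))
    @settings(max_examples=25, deadline=None)
    def test_shift_invariance(self, shift):
        angles = [3.0, 55.0, 120.0, 200.0]
        base = angle_dispersion(angles)
        moved = angle_dispersion([a + shift for a in angles])
        assert moved == pytest.approx(base, abs=1e-8)

    def test_von_mises_concentration_monotonicity(self):
        """Dispersion decreases as the fibre population concentrates."""
        rng = np.random.default_rng(12)
        disp = []
        for kappa in (0.5, 2.0, 8.0):
            angles = np.degrees(rng.vonmises(0.5, kappa, size=400))
            disp.append(angle_dispersion(angles))
        assert disp[0] > disp[1] > disp[2]

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError):
            angle_dispersion([10.0])
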