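"""Stiffness maps, setpoint-height segmentation and per-cell extraction."""

import numpy as np
import pytest

from mechanocyte import synthetic as syn
from mechanocyte.afm_mapping import (
    CellMechRecord,
    ForceMap,
    MaskEdit,
    SegmentationMask,
    StiffnessMap,
    apply_mask_edits,
    build_stiffness_map,
    extract_cell_mechanics,
    load_stiffness_map,
    profile_correlation,
    save_stiffness_map,
    segment_height_map,
)
from mechanocyte.force_spectroscopy import AcquisitionSettings, TipModel, simulate_force_curve


def two_bump_height(shape=(48, 48), centers=((14, 14), (32, 34)), radius=9.0, height=3.0):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    img = np.zeros(shape)
    labels = np.zeros(shape, dtype=int)
    for i, ctr in enumerate(centers, start=1):
        d = np.hypot(rr - ctr[0], cc - ctr[1])
        bump = np.where(d < radius, height * np.cos(np.pi * d / (2 * radius)) ** 2, 0.0)
        labels[bump > img] = np.where(bump[bump > img] > 0, i, labels[bump > img])
        img = np.maximum(img, bump)
    return img, labels


class TestBuildStiffnessMap:
    def test_cell_means_match_generator_truth(self, afm_pipeline):
        _, truth, smap, _ = afm_pipeline
        for lab, E_true in truth["cell_E"].items():
            sel = (truth["label_image"] == lab) & smap.quality_image
            assert abs(np.nanmean(smap.E_image[sel]) - E_true) / E_true < 0.05

    def test_uniform_substrate_low_cv(self):
        """Flat substrate-only curves give a nearly uniform modulus image."""
        rng = np.random.default_rng(5)
        settings = AcquisitionSettings(z_range=(0.0, 8.0), dz=0.02)
        tip = TipModel()
        curves = [
            simulate_force_curve(10000.0, tip, z0=4.0, noise_sd=0.02, settings=settings, seed=rng)
            for _ in range(144)
        ]
        fmap = ForceMap(curves, (12, 12), (15.0, 15.0))
        smap = build_stiffness_map(fmap, tip)
        E = smap.E_image[smap.quality_image]
        assert E.std() / E.mean() < 0.05

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            ForceMap([], (0, 0), (10.0, 10.0))


class TestSegmentHeightMap:
    def test_two_bumps_two_labels_covering_truth(self):
        # raw topographic bumps carry no soft-contact rim offset, so the
        # threshold floor is set below the bump shoulders explicitly
        height, true_labels = two_bump_height()
        mask = segment_height_map(height, sigma=1.0, min_offset=0.05)
        assert mask.n_cells == 2
        for i in (1, 2):
            truth = true_labels == i
            hits = np.bincount(mask.labels[truth], minlength=3)
            best = hits[1:].argmax() + 1
            assert hits[best] / truth.sum() >= 0.9

    def test_flat_image_gives_zero_labels(self):
        mask = segment_height_map(np.zeros((32, 32)))
        assert mask.n_cells == 0

    def test_touching_bumps_split_at_saddle(self):
        height, _ = two_bump_height(centers=((24, 14), (24, 30)), radius=10.0)
        mask = segment_height_map(height, sigma=1.0, min_offset=0.05)
        assert mask.n_cells == 2
        # the two labels sit on opposite sides of the saddle column
        cols = [np.argwhere(mask.labels == l)[:, 1].mean() for l in (1, 2)]
        assert min(cols) < 22 and max(cols) > 26

    def test_deterministic(self):
        height, _ = two_bump_height()
        a = segment_height_map(height).labels
        b = segment_height_map(height).labels
        np.testing.assert_array_equal(a, b)

    def test_manual_edit_script(self):
        height, _ = two_bump_height()
        merged = segment_height_map(height, manual_corrections=[MaskEdit("merge", labels=(1, 2))])
        assert merged.n_cells == 1
        assert merged.provenance == "manually corrected"
        deleted = segment_height_map(height, manual_corrections=[MaskEdit("delete", labels=(1,))])
        assert deleted.n_cells == 1
        auto = segment_height_map(height)
        split = apply_mask_edits(
            auto.labels,
            [MaskEdit("split", labels=(1,), seeds=((10, 10), (18, 18)))],
            height=height,
        )
        assert split.max() == 3


class TestExtractCellMechanics:
    @staticmethod
    def _smap(E_img, height=None, quality=None, px=1.0):
        E_img = np.asarray(E_img, dtype=float)
        return StiffnessMap(
            E_img,
            height if height is not None else np.ones_like(E_img),
            quality if quality is not None else np.ones(E_img.shape, dtype=bool),
            px,
        )

    def test_constant_field_mean_is_exact(self):
        E = np.full((10, 10), 997.0)
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[2:8, 2:8] = 1
        recs = extract_cell_mechanics(self._smap(E), SegmentationMask(labels))
        assert recs[0].mean_E == 997.0
        assert recs[0].area == 36.0

    def test_half_and_half_mean(self):
        E = np.full((4, 8), 600.0)
        E[:, 4:] = 800.0
        labels = np.ones((4, 8), dtype=np.int32)
        recs = extract_cell_mechanics(self._smap(E), SegmentationMask(labels))
        assert recs[0].mean_E == 700.0

    def test_matches_brute_force_loop(self, afm_pipeline):
        """Vectorised extraction equals an explicit per-pixel loop."""
        _, _, smap, mask = afm_pipeline
        recs = extract_cell_mechanics(smap, mask)
        for rec in recs:
            tot, n = 0.0, 0
            for r in range(mask.labels.shape[0]):
                for c in range(mask.labels.shape[1]):
                    if mask.labels[r, c] == rec.label and smap.quality_image[r, c]:
                        tot += smap.E_image[r, c]
                        n += 1
            assert n == rec.n_valid
            assert np.isclose(tot / n, rec.mean_E)

    def test_label_permutation_leaves_statistics_unchanged(self, afm_pipeline):
        _, _, smap, mask = afm_pipeline
        recs = {r.label: r for r in extract_cell_mechanics(smap, mask)}
        permuted = mask.labels.copy()
        permuted[mask.labels == 1] = 2
        permuted[mask.labels == 2] = 1
        recs_p = {r.label: r for r in extract_cell_mechanics(smap, SegmentationMask(permuted))}
        assert recs[1].mean_E == recs_p[2].mean_E
        assert recs[2].area == recs_p[1].area

    def test_all_invalid_label_flagged(self):
        E = np.full((6, 6), np.nan)
        labels = np.ones((6, 6), dtype=np.int32)
        quality = np.zeros((6, 6), dtype=bool)
        recs = extract_cell_mechanics(self._smap(E, quality=quality), SegmentationMask(labels))
        assert len(recs) == 1 and not recs[0].valid

    def test_end_to_end_cell_means(self, afm_pipeline):
        """Segmented per-cell mean E agrees with the generator within 5%."""
        _, truth, smap, mask = afm_pipeline
        assert mask.n_cells == len(truth["cell_E"])
        recs = extract_cell_mechanics(smap, mask)
        for rec in recs:
            sel = mask.labels == rec.label
            overlap = np.bincount(truth["label_image"][sel], minlength=3)
            true_lab = overlap[1:].argmax() + 1
            E_true = truth["cell_E"][true_lab]
            assert abs(rec.mean_E - E_true) / E_true < 0.05
            # the mask covers at least 90% of the generator's cell footprint
            covered = (mask.labels[truth["label_image"] == true_lab] == rec.label).mean()
            assert covered >= 0.9


class TestProfileCorrelation:
    def test_affine_profiles_perfectly_correlated(self):
        h = np.linspace(0, 3, 20)
        assert profile_correlation(h, 2 * h + 5) == pytest.approx(1.0)
        assert profile_correlation(h, -h) == pytest.approx(-1.0)

    def test_independent_noise_weakly_correlated(self, rng):
        assert abs(profile_correlation(rng.normal(size=64), rng.normal(size=64))) < 0.3

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            profile_correlation(np.ones(10), np.arange(10.0))


class TestMapIO:
    def test_tiff_round_trip(self, tmp_path, afm_pipeline):
        _, _, smap, _ = afm_pipeline
        path = tmp_path / "map.tif"
        save_stiffness_map(path, smap)
        loaded = load_stiffness_map(path)
        np.testing.assert_allclose(loaded.E_image, smap.E_image.astype(np.float32), equal_nan=True)
        np.testing.assert_array_equal(loaded.quality_image, smap.quality_image)
        assert loaded.pixel_size == smap.pixel_size
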