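"""Tests of tile fraction maps, mirrored ROIs, and beam/transverse profiles."""

import numpy as np
import pytest

from gfapquant.segment import SegmentSet, SegmentationParams
from gfapquant.tiles import (
    Profile,
    ROISpec,
    TileFractionMap,
    beam_axis_profile,
    compute_tile_fractions,
    define_mirrored_rois,
    mean_roi_fraction,
    tile_means,
    transverse_band_profiles,
)


def segset_from_mask(mask, pixel_size=1.0):
    """Wrap a binary mask as a single-label SegmentSet (areas unchecked)."""
    mask = np.asarray(mask, dtype=bool)
    return SegmentSet(
        label_map=mask.astype(np.int32),
        areas_um2=np.array([mask.sum() * pixel_size**2]) if mask.any() else np.empty(0),
        pixel_size=pixel_size,
        params_used=SegmentationParams(min_area_um2=0.1, max_area_um2=1e9),
    )


def nested_loop_fractions(mask, tile_px):
    """Oracle: per-tile pixel counting with explicit loops."""
    rows, cols = mask.shape
    nr = int(np.ceil(rows / tile_px))
    nc = int(np.ceil(cols / tile_px))
    pos = np.zeros((nr, nc))
    area = np.zeros((nr, nc))
    for i in range(nr):
        for j in range(nc):
            block = mask[i * tile_px : (i + 1) * tile_px, j * tile_px : (j + 1) * tile_px]
            pos[i, j] = block.sum()
            area[i, j] = block.size
    return pos / area


def uniform_map(nr, nc, value, tile_px=10, pixel_size=1.0):
    area = np.full((nr, nc), tile_px**2, dtype=np.int64)
    pos = (area * value).astype(np.int64)
    return TileFractionMap(
        positive_px=pos,
        tile_area_px=area,
        tile_size_um=tile_px * pixel_size,
        tile_px=tile_px,
        pixel_size=pixel_size,
    )


class TestComputeTileFractions:
    def test_empty_segments_all_zero(self):
        tmap = compute_tile_fractions(segset_from_mask(np.zeros((50, 50))), 10.0)
        assert not tmap.fractions.any()

    def test_saturated_tile(self):
        mask = np.zeros((20, 20), bool)
        mask[:10, :10] = True
        tmap = compute_tile_fractions(segset_from_mask(mask), 10.0)
        assert tmap.fractions[0, 0] == 1.0
        assert tmap.fractions[1, 1] == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_nested_loop_oracle(self, seed):
        r = np.random.default_rng(seed)
        mask = r.random((53, 47)) < 0.2  # deliberately not tile-divisible
        tmap = compute_tile_fractions(segset_from_mask(mask), 10.0)
        np.testing.assert_array_equal(tmap.fractions, nested_loop_fractions(mask, 10))

    def test_partial_edge_tiles_flagged(self):
        mask = np.zeros((25, 32), bool)
        tmap = compute_tile_fractions(segset_from_mask(mask), 10.0)
        assert tmap.full[:2, :3].all()
        assert not tmap.full[2, :].any()
        assert not tmap.full[:, 3].any()
        assert tmap.tile_area_px[2, 0] == 5 * 10

    def test_conservation_over_full_tiles(self, rng):
        mask = rng.random((53, 47)) < 0.3
        tmap = compute_tile_fractions(segset_from_mask(mask), 10.0)
        total = tmap.positive_px[tmap.full].sum()
        assert total == mask[:50, :40].sum()

    def test_tile_smaller_than_ten_pixels_rejected(self):
        with pytest.raises(ValueError, match="10 pixels"):
            compute_tile_fractions(segset_from_mask(np.zeros((30, 30))), 5.0)

    def test_tile_larger_than_image_warns(self):
        with pytest.warns(UserWarning, match="single-tile"):
            tmap = compute_tile_fractions(segset_from_mask(np.zeros((20, 20))), 50.0)
        assert tmap.shape == (1, 1)

    def test_tile_dose_means(self, rng):
        dose = rng.uniform(0, 45, (40, 40))
        tmap = compute_tile_fractions(segset_from_mask(np.zeros((40, 40))), 10.0)
        means = tile_means(dose, tmap)
        assert means[1, 2] == pytest.approx(dose[10:20, 20:30].mean())


class TestROIs:
    def test_reflection_offsets(self):
        right, left = define_mirrored_rois(
            image_shape=(200, 400),
            beam_axis_row=100.0,
            mirror_axis_col=199.5,
            roi_size_um=60.0,
            center_col_px=280.0,
            pixel_size=1.0,
        )
        assert right.rectangle == (70.0, 130.0, 250.0, 310.0)
        assert left.rectangle == (70.0, 130.0, 89.0, 149.0)
        # equidistant from the mirror axis
        assert right.rectangle[2] - 199.5 == pytest.approx(199.5 - left.rectangle[3])

    def test_double_reflection_is_identity(self):
        right, left = define_mirrored_rois((200, 400), 100.0, 199.5, 60.0, 280.0, 1.0)
        assert left.mirrored().rectangle == right.rectangle

    def test_physical_size_in_pixels(self):
        right, _ = define_mirrored_rois((3000, 4000), 1500.0, 1999.5, 2400.0, 2800.0, 2.0)
        r0, r1, c0, c1 = right.rectangle
        assert r1 - r0 == pytest.approx(1200.0)  # 2.4 mm at 2 um/px
        assert c1 - c0 == pytest.approx(1200.0)

    def test_crossing_mirror_axis_rejected(self):
        with pytest.raises(ValueError, match="cross|fit"):
            define_mirrored_rois((200, 400), 100.0, 199.5, 60.0, 210.0, 1.0)

    def test_roi_outside_image_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            define_mirrored_rois((200, 400), 100.0, 199.5, 150.0, 350.0, 1.0)


class TestMeanRoiFraction:
    def test_uniform_map(self):
        tmap = uniform_map(10, 10, 0.25)
        roi = ROISpec((5.0, 60.0, 10.0, 70.0), "right", 5.0)
        assert mean_roi_fraction(tmap, roi) == pytest.approx(0.25)

    def test_two_tile_mean(self):
        tmap = uniform_map(1, 4, 0.0)
        tmap.positive_px[0, 2] = 10  # fraction 0.1
        tmap.positive_px[0, 3] = 30  # fraction 0.3
        roi = ROISpec((0.0, 9.0, 20.0, 39.0), "right", 10.0)
        assert mean_roi_fraction(tmap, roi) == pytest.approx(0.2)

    def test_matches_enumeration_oracle(self, rng):
        tmap = uniform_map(8, 9, 0.0)
        tmap.positive_px[:] = rng.integers(0, 100, (8, 9))
        roi = ROISpec((12.0, 61.0, 33.0, 77.0), "right", 1.0)
        rows_c = tmap.tile_center_rows()
        cols_c = tmap.tile_center_cols()
        vals = [
            tmap.fractions[i, j]
            for i in range(8)
            for j in range(9)
            if 12.0 <= rows_c[i] <= 61.0 and 33.0 <= cols_c[j] <= 77.0
        ]
        assert mean_roi_fraction(tmap, roi) == pytest.approx(np.mean(vals))

    def test_mirror_consistency_on_symmetric_map(self, rng):
        # tile area 256 px makes every fraction dyadic, so the means are
        # exactly equal independent of summation order
        half = rng.integers(0, 257, (6, 5))
        pos = np.concatenate([half, half[:, ::-1]], axis=1)
        tmap = uniform_map(6, 10, 0.0, tile_px=16)
        tmap.positive_px[:] = pos
        m = 10 * 16 / 2 - 0.5  # mirror between tile columns 4 and 5
        right = ROISpec((0.0, 95.0, m + 1, m + 49), "right", m)
        assert mean_roi_fraction(tmap, right) == mean_roi_fraction(tmap, right.mirrored())

    def test_no_tiles_in_roi_rejected(self):
        tmap = uniform_map(5, 5, 0.1)
        roi = ROISpec((1.0, 2.0, 1.0, 2.0), "right", 0.5)
        with pytest.raises(ValueError, match="no full tile"):
            mean_roi_fraction(tmap, roi)


class TestProfiles:
    def test_uniform_map_flat_profile(self):
        tmap = uniform_map(10, 12, 0.2)
        dose = np.zeros((100, 120))
        roi = ROISpec((20.0, 79.0, 70.0, 119.0), "right", 59.5)
        prof = beam_axis_profile(tmap, dose, roi)
        np.testing.assert_allclose(prof.gfap_means, 0.2)
        assert prof.positions_um.size == 12  # spans the full slice

    def test_dose_profile_peak_position(self, rng):
        tmap = uniform_map(10, 12, 0.1)
        rr, cc = np.meshgrid(np.arange(100.0), np.arange(120.0), indexing="ij")
        dose = 45.0 * np.exp(-((cc - 83.0) ** 2) / 300.0)
        roi = ROISpec((20.0, 79.0, 70.0, 119.0), "right", 59.5)
        prof = beam_axis_profile(tmap, dose, roi)
        # oracle: argmax of directly computed tile means
        means = tile_means(dose, tmap)
        row_sel = (tmap.tile_center_rows() >= 20.0) & (tmap.tile_center_rows() <= 79.0)
        expected = prof.positions_um[np.argmax(means[row_sel].mean(axis=0))]
        assert prof.positions_um[np.argmax(prof.dose_means)] == expected

    def test_band_profiles_match_enumeration_oracle(self, rng):
        tmap = uniform_map(9, 14, 0.0)
        tmap.positive_px[:] = rng.integers(0, 100, (9, 14))
        dose = rng.uniform(0, 45, (90, 140))
        cortex = ROISpec((0.0, 89.0, 110.0, 139.0), "right", 69.5)
        central = ROISpec((0.0, 89.0, 75.0, 105.0), "right", 69.5)
        cortex_p, central_p = transverse_band_profiles(tmap, dose, cortex, central)
        cols_c = tmap.tile_center_cols()
        sel = (cols_c >= 110.0) & (cols_c <= 139.0)
        for i, pos in enumerate(cortex_p.positions_um):
            row = int((pos / tmap.pixel_size + 0.5) / tmap.tile_px - 0.5 + 1e-9)
            assert cortex_p.gfap_means[i] == pytest.approx(
                tmap.fractions[row, sel].mean()
            )

    def test_identical_band_content_gives_identical_profiles(self, rng):
        half = rng.integers(0, 100, (6, 7))
        pos = np.concatenate([half, half[:, ::-1]], axis=1)
        tmap = uniform_map(6, 14, 0.0)
        tmap.positive_px[:] = pos
        dose = np.zeros((60, 140))
        m = 69.5
        right_band = ROISpec((0.0, 59.0, 100.0, 129.0), "right", m)
        left_band = right_band.mirrored()
        p_r, p_l = transverse_band_profiles(tmap, dose, right_band, left_band)
        np.testing.assert_allclose(p_r.gfap_means, p_l.gfap_means)

    def test_overlapping_bands_rejected(self):
        tmap = uniform_map(6, 14, 0.1)
        a = ROISpec((0.0, 59.0, 80.0, 110.0), "right", 69.5)
        b = ROISpec((0.0, 59.0, 100.0, 130.0), "right", 69.5)
        with pytest.raises(ValueError, match="overlap"):
            transverse_band_profiles(tmap, np.zeros((60, 140)), a, b)

    def test_profile_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            Profile(np.arange(3.0), np.arange(2.0), np.arange(3.0), "along-beam", "ROI")


class TestPhantomProfiles:
    def test_sham_band_contrast_cortex_below_central(self, sham_small):
        from gfapquant.pipeline import PipelineConfig, default_bands, default_rois
        from gfapquant.segment import segment_slice

        cfg = PipelineConfig.small()
        segs, _ = segment_slice(sham_small.gfap)
        tmap = compute_tile_fractions(segs, cfg.tile_size_um)
        cortex_band, central_band = default_bands(cfg)
        cortex_p, central_p = transverse_band_profiles(
            tmap, sham_small.truth.dose_px, cortex_band, central_band
        )
        assert cortex_p.gfap_means.mean() < central_p.gfap_means.mean()
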