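import numpy as np
import pytest

from canalseg.errors import CanalSegError, DegenerateInputError, NoBoneDetectedError
from canalseg.mandible_roi import (
    PanoramicView,
    center_third,
    extract_mandible_roi,
    largest_components,
    morph,
    multi_otsu,
    reconstruct_panorama,
    _quantize,
)
from canalseg.phantom import DEFAULT_INTENSITIES
from canalseg.volume_io import BinaryMask, Volume

from oracles import exhaustive_multi_otsu


class TestMultiOtsu:
    def test_bimodal_single_threshold_separates_modes(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.random((100, 100)) < 0.6, 10.0, 200.0)
        ts = multi_otsu(img, n_levels=1)
        assert 10.0 < ts.levels[0] < 200.0

    def test_trimodal_matches_exhaustive_search(self):
        rng = np.random.default_rng(1)
        img = np.concatenate(
            [
                rng.normal(30, 6, 4000),
                rng.normal(120, 10, 3000),
                rng.normal(220, 8, 2000),
            ]
        )
        ts = multi_otsu(img, n_levels=3)
        hist, centers = _quantize(img)
        oracle, _var = exhaustive_multi_otsu(hist, centers, n_levels=3)
        assert ts.levels == pytest.approx(oracle, abs=1e-12)

    def test_quiet_phantom_levels_bracket_tissue_intensities(self, quiet_phantom):
        ts = multi_otsu(quiet_phantom.volume)
        i = DEFAULT_INTENSITIES
        assert ts.bone < i["trabecular"]
        assert i["cortical"] <= ts.teeth < i["tooth"]

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            multi_otsu(np.full((10, 10), 3.0))
        with pytest.raises(DegenerateInputError):
            multi_otsu(np.repeat([0.0, 1.0], 50), n_levels=3)


class TestPanorama:
    def test_zero_volume_projects_to_zero(self):
        pano = reconstruct_panorama(Volume(np.zeros((5, 6, 7)), (1, 1, 1)))
        assert pano.image.shape == (7, 5)
        assert not pano.image.any()

    def test_single_bright_voxel_lands_at_x_z(self):
        data = np.zeros((8, 9, 10))
        data[3, 5, 6] = 4.0
        pano = reconstruct_panorama(Volume(data, (1, 1, 1)))
        assert pano.image[6, 3] == 4.0
        assert np.count_nonzero(pano.image) == 1

    def test_row_count_equals_nz(self, default_phantom):
        pano = reconstruct_panorama(default_phantom.volume)
        assert pano.image.shape[0] == default_phantom.volume.data.shape[2]

    @pytest.mark.parametrize("width,lo,hi", [(9, 3, 6), (10, 3, 6), (12, 4, 8)])
    def test_center_third_floor_convention(self, width, lo, hi):
        view = PanoramicView(np.zeros((4, width)), np.arange(width), (1.0, 1.0))
        out = center_third(view)
        np.testing.assert_array_equal(out.col_to_x, np.arange(lo, hi))

    def test_center_third_needs_width_three(self):
        with pytest.raises(CanalSegError):
            center_third(PanoramicView(np.zeros((4, 2)), np.arange(2), (1.0, 1.0)))


class TestLargestComponents:
    def test_single_blob_identity(self):
        m = np.zeros((10, 10), dtype=bool)
        m[2:5, 2:5] = True
        np.testing.assert_array_equal(largest_components(m, 1).data, m)

    def test_keeps_two_largest_of_three(self):
        m = np.zeros((40, 40), dtype=bool)
        m[0:10, 0:10] = True  # 100
        m[20:25, 20:30] = True  # 50
        m[35:37, 35:40] = True  # 10
        out = largest_components(m, 2).data
        assert out[:10, :10].all() and out[20:25, 20:30].all()
        assert not out[35:37, 35:40].any()

    def test_k_larger_than_component_count_keeps_all(self):
        m = np.zeros((20, 20), dtype=bool)
        m[0, 0] = m[5, 5] = m[10, 10] = True
        np.testing.assert_array_equal(largest_components(m, 5).data, m)

    def test_empty_mask_warns_not_raises(self):
        with pytest.warns(UserWarning):
            out = largest_components(np.zeros((4, 4), dtype=bool), 1)
        assert not out.data.any()


class TestMorph:
    def test_complement_is_involution(self):
        rng = np.random.default_rng(2)
        m = BinaryMask(rng.random((6, 7, 8)) > 0.5, (1, 1, 1))
        np.testing.assert_array_equal(morph(morph(m, "complement"), "complement").data, m.data)

    def test_closing_is_identity_on_a_digital_ball(self):
        g = np.indices((25, 25, 25)).astype(float)
        ball = np.sqrt(((g - 12) ** 2).sum(axis=0)) <= 7.0
        m = BinaryMask(ball, (1.0, 1.0, 1.0))
        closed = morph(morph(m, "dilate", 3.0), "erode", 3.0)
        np.testing.assert_array_equal(closed.data, ball)
        # and closing is extensive on arbitrary shapes
        rng = np.random.default_rng(3)
        blob = rng.random((20, 20, 20)) > 0.7
        cl = morph(BinaryMask(blob, (1, 1, 1)), "close", 2.0)
        assert np.all(cl.data[blob])

    def test_closing_fills_internal_hole(self):
        g = np.indices((25, 25, 25)).astype(float)
        d = np.sqrt(((g - 12) ** 2).sum(axis=0))
        mask = (d <= 8) & ~(d <= 2)
        closed = morph(BinaryMask(mask, (1, 1, 1)), "close", 3.0)
        assert closed.data[12, 12, 12]

    def test_anisotropic_spacing_respected(self):
        m = np.zeros((11, 11), dtype=bool)
        m[5, 5] = True
        out = morph(BinaryMask(m, (1.0, 2.0)), "dilate", 2.0)
        assert out.data[3, 5] and out.data[7, 5]  # 2 voxels along the 1 mm axis
        assert out.data[5, 4] and out.data[5, 6]  # 1 voxel along the 2 mm axis
        assert not out.data[5, 3] and not out.data[5, 7]


class TestExtractROI:
    def test_canal_contained_and_maxilla_excluded(self, default_phantom, default_roi):
        canal = default_phantom.canal_mask.data
        frac_in = canal[default_roi.box.slices].sum() / canal.sum()
        assert frac_in >= 0.99
        mx = default_phantom.maxilla_mask.data
        in_roi = (mx & default_roi.mandible_mask.data).sum() / mx.sum()
        assert 1.0 - in_roi >= 0.95

    def test_roi_shrinks_volume(self, default_phantom, default_roi):
        ratio = np.prod(default_roi.box.shape) / default_phantom.volume.data.size
        assert ratio <= 0.5

    def test_cropped_voxels_outside_mask_are_air(self, default_phantom, default_roi):
        sub_mask = default_roi.mandible_mask.data[default_roi.box.slices]
        fill = default_phantom.volume.data.min()
        assert np.all(default_roi.cropped.data[~sub_mask] == fill)

    def test_pipeline_deterministic(self, default_phantom, default_roi):
        again = extract_mandible_roi(default_phantom.volume)
        assert again.box == default_roi.box
        np.testing.assert_array_equal(again.mandible_mask.data, default_roi.mandible_mask.data)
        assert again.thresholds.levels == default_roi.thresholds.levels

    def test_all_air_volume_reports_no_bone(self):
        with pytest.raises(NoBoneDetectedError):
            extract_mandible_roi(Volume(np.zeros((50, 50, 50)), (1, 1, 1)))

    def test_manual_overrides_bypass_otsu(self, default_phantom):
        roi = extract_mandible_roi(
            default_phantom.volume, bone_threshold=0.2, teeth_threshold=0.8
        )
        assert roi.thresholds.bone == 0.2 and roi.thresholds.teeth == 0.8
        canal = default_phantom.canal_mask.data
        assert canal[roi.box.slices].sum() / canal.sum() >= 0.99

    def test_intermediates_cover_steps_a_to_i(self, default_phantom):
        roi = extract_mandible_roi(default_phantom.volume, save_intermediates=True)
        assert set("ABCDEFGHI") <= set(roi.intermediates)
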