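"""Resampling, skull stripping, normalization and binarization."""

import numpy as np
import pytest

from conftest import make_mask, make_volume
from fcdseg import (
    PreprocessConfig,
    Preprocessor,
    binarize_mask,
    normalize_intensity,
    preprocess_case,
    resample,
    skull_strip,
)
from fcdseg.exceptions import DegenerateInputError
from fcdseg.metrics import dice
from fcdseg.phantom import PhantomSpec, generate_phantom
from fcdseg.preprocess import resample_mask


class TestResample:
    def test_shape_follows_spacing_ratio(self):
        vol = make_volume(np.zeros((40, 40, 40)), spacing=(1, 1, 1))
        out = resample(vol, (2.0, 2.0, 2.0), order=1)
        assert out.shape == (20, 20, 20)
        np.testing.assert_allclose(out.spacing, (2, 2, 2))

    @pytest.mark.parametrize(
        "shape,spacing,target",
        [((10, 20, 30), (1, 1, 1), (0.5, 2.0, 3.0)),
         ((9, 9, 9), (0.7, 0.7, 3.0), (1.0, 1.0, 1.0)),
         ((5, 5, 5), (1, 1, 1), (10.0, 10.0, 10.0))],
    )
    def test_closed_form_shape_rule(self, shape, spacing, target):
        expected = tuple(
            max(1, int(round(s * sp / t))) for s, sp, t in zip(shape, spacing, target)
        )
        out = resample(make_volume(np.zeros(shape), spacing), target, order=1)
        assert out.shape == expected

    def test_identity_resampling_preserves_data(self):
        rng = np.random.default_rng(3)
        vol = make_volume(rng.normal(size=(8, 8, 8)))
        out = resample(vol, (1.0, 1.0, 1.0), order=3)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-6)
        assert out.shape == vol.shape

    def test_constant_field_preserved(self):
        vol = make_volume(np.full((12, 10, 8), 42.0))
        out = resample(vol, (2.0, 2.0, 2.0), order=3)
        np.testing.assert_allclose(out.data, 42.0, atol=1e-9)

    def test_world_extent_preserved_within_a_voxel(self):
        vol = make_volume(np.zeros((40, 40, 40)), spacing=(1, 1, 1))
        out = resample(vol, (2.0, 2.0, 2.0), order=1)
        old_extent = np.array(vol.shape) * vol.spacing
        new_extent = np.array(out.shape) * out.spacing
        assert np.all(np.abs(old_extent - new_extent) <= out.spacing)

    def test_non_positive_spacing_rejected(self):
        vol = make_volume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            resample(vol, (1.0, 0.0, 1.0))

    def test_mask_resampling_keeps_labels_binary(self):
        rng = np.random.default_rng(5)
        mask = make_mask((rng.random((16, 16, 16)) > 0.7).astype(np.uint8))
        down = resample_mask(mask, (2.0, 2.0, 2.0))
        assert set(np.unique(down.data)) <= {0, 1}
        assert down.shape == (8, 8, 8)


class TestSkullStrip:
    def test_recovers_phantom_brain(self, phantom_with_info):
        vol, _, info = phantom_with_info
        stripped, brain = skull_strip(vol)
        assert dice(brain, info.brain_mask) >= 0.95
        assert np.all(stripped.data[~brain] == 0)

    def test_brain_mask_is_single_component(self, phantom_with_info):
        from scipy import ndimage

        _, brain = skull_strip(phantom_with_info[0])
        _, n = ndimage.label(brain, structure=ndimage.generate_binary_structure(3, 1))
        assert n == 1
        assert brain.any()

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            skull_strip(make_volume(np.full((6, 6, 6), 7.0)))

    def test_small_bright_satellite_excluded(self):
        data = np.zeros((40, 40, 40))
        zz = np.indices(data.shape)
        center = ((zz[0] - 20.0) / 12) ** 2 + ((zz[1] - 20.0) / 12) ** 2 + ((zz[2] - 20.0) / 10) ** 2
        data[center <= 1] = 100.0
        data[1:4, 1:4, 1:4] = 120.0  # non-brain satellite blob
        _, brain = skull_strip(make_volume(data))
        assert not brain[1:4, 1:4, 1:4].any()
        assert brain[20, 20, 20]


class TestNormalize:
    def test_zero_mean_unit_sd_inside_mask(self, phantom_with_info):
        vol, _, info = phantom_with_info
        out = normalize_intensity(vol, info.brain_mask)
        vals = out.data[info.brain_mask]
        assert abs(vals.mean()) < 1e-6
        assert abs(vals.std() - 1.0) < 1e-6
        assert np.all(out.data[~info.brain_mask] == 0)

    def test_idempotent(self, phantom_with_info):
        vol, _, info = phantom_with_info
        once = normalize_intensity(vol, info.brain_mask)
        twice = normalize_intensity(once, info.brain_mask)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-6)

    def test_invariant_under_positive_affine_intensity_map(self, phantom_with_info):
        vol, _, info = phantom_with_info
        shifted = vol.with_data(3.2 * vol.data - 40.0)
        np.testing.assert_allclose(
            normalize_intensity(shifted, info.brain_mask).data,
            normalize_intensity(vol, info.brain_mask).data,
            atol=1e-6,
        )

    def test_zero_variance_rejected(self):
        vol = make_volume(np.full((4, 4, 4), 9.0))
        with pytest.raises(DegenerateInputError):
            normalize_intensity(vol, np.ones((4, 4, 4), dtype=bool))

    def test_empty_mask_rejected(self):
        vol = make_volume(np.random.default_rng(0).normal(size=(4, 4, 4)))
        with pytest.raises(DegenerateInputError):
            normalize_intensity(vol, np.zeros((4, 4, 4), dtype=bool))


class TestBinarize:
    def test_threshold_rule(self):
        raw = np.array([0.0, 0.4, 0.6, 1.0]).reshape(1, 2, 2)
        np.testing.assert_array_equal(
            binarize_mask(raw, 0.5).ravel(), [0, 0, 1, 1]
        )

    def test_all_zero_stays_zero(self):
        assert binarize_mask(np.zeros((3, 3, 3))).sum() == 0

    def test_idempotent_on_binary_input(self):
        raw = (np.arange(8).reshape(2, 2, 2) % 2).astype(float)
        np.testing.assert_array_equal(binarize_mask(raw, 0.5), raw)

    def test_non_finite_rejected(self):
        raw = np.zeros((2, 2, 2))
        raw[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            binarize_mask(raw)


class TestPreprocessCase:
    def test_identity_config_is_noop(self, phantom_with_info):
        vol, mask, _ = phantom_with_info
        cfg = PreprocessConfig(target_spacing=None, normalization="none", skullstrip_method="none")
        out_v, out_m = preprocess_case(vol, mask, cfg)
        np.testing.assert_array_equal(out_v.data, vol.data)
        np.testing.assert_array_equal(out_m.data, mask.data)

    def test_native_spacing_keeps_lesion_count(self, phantom_with_info):
        vol, mask, _ = phantom_with_info
        out_v, out_m = preprocess_case(vol, mask, PreprocessConfig(target_spacing=(1, 1, 1)))
        assert out_m.lesion_voxels == mask.lesion_voxels
        assert out_v.shape == vol.shape

    def test_downsampled_mask_stays_binary_and_nonempty(self, phantom_with_info):
        vol, mask, _ = phantom_with_info
        out_v, out_m = preprocess_case(vol, mask, PreprocessConfig(target_spacing=(2, 2, 2)))
        assert set(np.unique(out_m.data)) <= {0, 1}
        assert out_m.lesion_voxels > 0  # lesion radius >= 3 voxels survives 2x downsampling
        assert out_v.shape == out_m.shape

    def test_errors_are_annotated_with_stage_name(self):
        vol = make_volume(np.full((6, 6, 6), 5.0))
        mask = make_mask(np.zeros((6, 6, 6), dtype=np.uint8))
        with pytest.raises(DegenerateInputError, match=r"\[skull_strip\]"):
            preprocess_case(vol, mask, PreprocessConfig(target_spacing=None))


def test_preprocessor_transformer_round_trip(phantom_with_info):
    vol, mask, _ = phantom_with_info
    est = Preprocessor(target_spacing=(1.0, 1.0, 1.0))
    pairs = est.fit_transform([(vol, mask)])
    assert len(pairs) == 1
    out_v, out_m = pairs[0]
    vals = out_v.data[out_v.data != 0]
    assert abs(vals.mean()) < 0.1  # z-scored brain (zeros excluded shift the mean slightly)
    params = est.get_params()
    assert params["target_spacing"] == (1.0, 1.0, 1.0)
    assert Preprocessor(**params).get_params() == params
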