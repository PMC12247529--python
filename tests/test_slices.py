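"""Slice scoring, top-k selection, slab extraction and their invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import top_k_bruteforce
from conftest import make_mask, make_volume
from fcdseg import (
    SliceRanking,
    SliceSelector,
    extract_slab,
    score_slices,
    select_case,
    select_top_k,
)
from fcdseg.exceptions import ConfigurationError
from fcdseg.phantom import PhantomSpec, generate_phantom


def staircase_fixture():
    """5-slice volume whose per-slice lesion counts are (0, 3, 7, 7, 1)."""
    mask = np.zeros((4, 4, 5), dtype=np.uint8)
    for z, count in enumerate([0, 3, 7, 7, 1]):
        mask[:, :, z].flat[:count] = 1
    vol = make_volume(np.random.default_rng(0).normal(100, 5, (4, 4, 5)))
    return vol, make_mask(mask)


class TestScoreSlices:
    def test_lesion_area_counts_mask_voxels(self):
        vol, mask = staircase_fixture()
        ranking = score_slices(vol, mask, criterion="lesion_area")
        np.testing.assert_array_equal(ranking.scores, [0, 3, 7, 7, 1])

    def test_lesion_area_on_empty_mask_is_zero(self):
        vol, _ = staircase_fixture()
        empty = make_mask(np.zeros((4, 4, 5), dtype=np.uint8))
        assert score_slices(vol, empty, "lesion_area").scores.sum() == 0

    def test_peak_intensity_is_per_slice_maximum(self):
        data = np.full((3, 3, 4), 5.0)
        data[1, 1, 2] = 9.0
        ranking = score_slices(make_volume(data), criterion="peak_intensity")
        assert ranking.scores[2] == 9.0
        assert np.all(ranking.scores[[0, 1, 3]] == 5.0)

    def test_lesion_area_without_mask_is_a_configuration_error(self):
        vol, _ = staircase_fixture()
        with pytest.raises(ConfigurationError):
            score_slices(vol, None, "lesion_area")

    def test_scores_length_equals_axial_extent_for_any_axial_axis(self):
        data = np.random.default_rng(1).normal(size=(4, 6, 5))
        vol = make_volume(data, axial_axis=1)
        assert score_slices(vol, criterion="peak_intensity").scores.size == 6


class TestSelectTopK:
    def test_hand_examples(self):
        r = SliceRanking(np.array([5.0, 1, 9, 3, 7]), "peak_intensity")
        np.testing.assert_array_equal(select_top_k(r, 3).selected, [0, 2, 4])
        r = SliceRanking(np.array([7.0, 7, 7]), "peak_intensity")
        np.testing.assert_array_equal(select_top_k(r, 2).selected, [0, 1])

    def test_k_beyond_slice_count_selects_all(self):
        r = SliceRanking(np.array([1.0, 2.0]), "lesion_area")
        np.testing.assert_array_equal(select_top_k(r, 99).selected, [0, 1])

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            select_top_k(SliceRanking(np.ones(3), "lesion_area"), 0)

    def test_agrees_with_exhaustive_oracle_on_random_scores(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 9))
            scores = rng.integers(0, 4, n).astype(float)  # small range forces ties
            k = int(rng.integers(1, n + 1))
            got = select_top_k(SliceRanking(scores, "lesion_area"), k).selected
            assert got.tolist() == top_k_bruteforce(scores.tolist(), k)

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=8), st.integers(1, 8))
    def test_agrees_with_exhaustive_oracle_property(self, scores, k):
        got = select_top_k(SliceRanking(np.array(scores, float), "lesion_area"), k).selected
        assert got.tolist() == top_k_bruteforce(scores, k)


class TestExtractSlab:
    def test_identity_slab(self):
        vol, mask = staircase_fixture()
        slab_v, slab_m = extract_slab(vol, mask, np.arange(5))
        np.testing.assert_array_equal(slab_v.data, vol.data)
        np.testing.assert_array_equal(slab_m.data, mask.data)
        np.testing.assert_allclose(slab_v.affine, vol.affine)

    def test_single_slice_slab(self):
        vol, mask = staircase_fixture()
        slab_v, _ = extract_slab(vol, mask, [2])
        assert slab_v.shape == (4, 4, 1)
        np.testing.assert_array_equal(slab_v.data[:, :, 0], vol.data[:, :, 2])

    def test_axial_origin_moves_to_first_selected_slice(self):
        vol, mask = staircase_fixture()
        slab_v, _ = extract_slab(vol, mask, [2, 4])
        np.testing.assert_allclose(slab_v.affine[:3, 3], vol.affine[:3, 3] + [0, 0, 2])
        np.testing.assert_allclose(slab_v.spacing, vol.spacing)  # nominal axial spacing kept

    def test_out_of_bounds_index(self):
        vol, mask = staircase_fixture()
        with pytest.raises(IndexError):
            extract_slab(vol, mask, [3, 7])

    def test_full_selection_keeps_all_lesion_voxels(self):
        vol, mask = staircase_fixture()
        _, slab_m, _ = select_case(vol, mask, "lesion_area", k=5)
        assert slab_m.lesion_voxels == 18 == mask.lesion_voxels


class TestSelectCase:
    def test_lesion_spanning_k_slices_fully_retained(self):
        vol, mask, _ = generate_phantom(PhantomSpec(seed=21), with_info=True)
        bearing = int((np.moveaxis(mask.data, 2, 0).reshape(mask.shape[2], -1).sum(1) > 0).sum())
        _, slab_m, _ = select_case(vol, mask, "lesion_area", k=bearing)
        assert slab_m.lesion_voxels == mask.lesion_voxels

    def test_short_volume_yields_short_slab(self):
        data = np.random.default_rng(0).normal(size=(3, 3, 4))
        vol = make_volume(data)
        mask = make_mask(np.zeros((3, 3, 4), dtype=np.uint8))
        slab_v, _, _ = select_case(vol, mask, "peak_intensity", k=5)
        assert slab_v.shape[2] == 4

    def test_deterministic(self):
        vol, mask, _ = generate_phantom(PhantomSpec(seed=5), with_info=True)
        a = select_case(vol, mask, "lesion_area", k=5)
        b = select_case(vol, mask, "lesion_area", k=5)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[2].selected, b[2].selected)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_selection_enriches_lesion_fraction(self, seed):
        vol, mask = generate_phantom(PhantomSpec(seed=seed))
        _, slab_m, _ = select_case(vol, mask, "lesion_area", k=5)
        full_fraction = mask.lesion_voxels / mask.data.size
        slab_fraction = slab_m.lesion_voxels / slab_m.data.size
        assert slab_fraction >= full_fraction > 0


def test_slice_selector_transformer_records_rankings(phantom_with_info):
    vol, mask, _ = phantom_with_info
    sel = SliceSelector(k=5)
    slabs = sel.fit_transform([(vol, mask)])
    assert slabs[0][0].shape[2] == 5
    assert len(sel.rankings_) == 1
    report = sel.rankings_[0].to_frame()
    assert report["selected"].sum() == 5
    assert len(report) == vol.shape[2]
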