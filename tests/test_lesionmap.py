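"""Tests for voxelwise lesion cartography."""
import logging

import numpy as np
import pandas as pd
import pytest

from oataxia import lesionmap as lm


def _mask(data, voxel=1.0):
    return lm.VolumeGrid(np.asarray(data, dtype=np.uint8), (voxel,) * 3)


def _random_mask(rng, shape=(10, 9, 8), p=0.2, voxel=1.0):
    return _mask(rng.random(shape) < p, voxel)


class TestVolumeIO:
    def test_round_trip_preserves_mask(self, rng, tmp_path):
        grid = _random_mask(rng)
        path = tmp_path / "m.nii.gz"
        lm.write_volume(grid, path)
        back = lm.read_volume(path)
        assert np.array_equal(back.voxels, grid.voxels)
        assert back.voxel_size == grid.voxel_size

    def test_non_binary_mask_rejected(self):
        bad = lm.VolumeGrid(np.full((3, 3, 3), 2, dtype=np.int16))
        with pytest.raises(ValueError, match="binary"):
            lm.lesion_volume(bad)

    def test_atlas_label_inventory(self, toy_atlas):
        inv = toy_atlas.label_inventory()
        assert sorted(inv.index) == sorted(toy_atlas.labels)
        assert (inv > 0).all()

    def test_grid_mismatch_detected(self, rng):
        a = _random_mask(rng, shape=(5, 5, 5))
        b = _random_mask(rng, shape=(5, 5, 6))
        with pytest.raises(lm.GridMismatchError):
            lm.overlap_map([a, b])


class TestFlip:
    def test_involution(self, rng):
        m = _random_mask(rng)
        flipped = lm.flip_to_reference_hemisphere(m, "left", "right")
        twice = lm.mirror(flipped)
        assert np.array_equal(twice.voxels, m.voxels)

    def test_single_voxel_lands_on_mirrored_index(self):
        data = np.zeros((7, 5, 5), dtype=np.uint8)
        data[1, 2, 3] = 1
        flipped = lm.flip_to_reference_hemisphere(_mask(data), "left", "right")
        assert flipped.voxels[5, 2, 3] == 1
        assert flipped.voxels.sum() == 1

    def test_volume_conserved_and_right_unchanged(self, rng):
        m = _random_mask(rng)
        flipped = lm.flip_to_reference_hemisphere(m, "left")
        assert flipped.voxels.sum() == m.voxels.sum()
        same = lm.flip_to_reference_hemisphere(m, "right")
        assert np.array_equal(same.voxels, m.voxels)


class TestLesionVolume:
    @pytest.mark.parametrize(
        "n_voxels, voxel, expected",
        [(0, 1.0, 0.0), (100, 1.0, 100.0), (100, 0.5, 12.5)],
    )
    def test_examples(self, n_voxels, voxel, expected):
        data = np.zeros((10, 10, 10), dtype=np.uint8)
        data.ravel()[:n_voxels] = 1
        assert lm.lesion_volume(_mask(data, voxel)) == pytest.approx(expected)


class TestNucleusDamage:
    def test_lesion_superset_of_nucleus_is_fully_damaged(self, toy_atlas):
        mask = toy_atlas.volume.like((toy_atlas.volume.voxels > 0).astype(np.uint8))
        prof = lm.nucleus_damage_profile(mask, toy_atlas)
        assert (prof["pct_nucleus_damaged"] == 100.0).all()
        assert prof["affected"].all()

    def test_disjoint_lesion_not_affected(self, toy_atlas):
        data = np.zeros(toy_atlas.volume.shape, dtype=np.uint8)
        data[0, 0, 0] = 1  # far corner, outside every nucleus
        prof = lm.nucleus_damage_profile(toy_atlas.volume.like(data), toy_atlas)
        assert (prof["pct_nucleus_damaged"] == 0.0).all()
        assert not prof["affected"].any()

    def test_matches_brute_force_voxel_loop(self, rng, toy_atlas):
        mask = toy_atlas.volume.like(
            (rng.random(toy_atlas.volume.shape) < 0.1).astype(np.uint8)
        )
        prof = lm.nucleus_damage_profile(mask, toy_atlas)
        labels = toy_atlas.volume.voxels
        for value, name in toy_atlas.labels.items():
            expected = int(np.sum((labels == value) & (mask.voxels == 1)))
            assert prof.loc[name, "damaged_voxels"] == expected


class TestTerritory:
    def test_pulvinar_lesion_is_posterior(self, toy_atlas):
        pu_labels = [v for v, n in toy_atlas.labels.items() if n.startswith("Pu")]
        mask = toy_atlas.volume.like(
            np.isin(toy_atlas.volume.voxels, pu_labels).astype(np.uint8)
        )
        prof = lm.nucleus_damage_profile(mask, toy_atlas)
        assert lm.territory_classification(prof) == "posterior"

    def test_majority_rule(self):
        prof = pd.DataFrame(
            {
                "territory": ["lateral", "medial"],
                "damaged_voxels": [60, 40],
            },
            index=pd.Index(["VL", "CM"], name="nucleus"),
        )
        assert lm.territory_classification(prof) == "lateral"

    def test_no_overlap_is_other(self, toy_atlas, caplog):
        data = np.zeros(toy_atlas.volume.shape, dtype=np.uint8)
        data[0, 0, 0] = 1
        prof = lm.nucleus_damage_profile(toy_atlas.volume.like(data), toy_atlas)
        with caplog.at_level(logging.WARNING):
            assert lm.territory_classification(prof) == "other"


class TestLaterality:
    def test_unilateral(self):
        data = np.zeros((10, 4, 4), dtype=np.uint8)
        data[:4, :2, :2] = 1
        assert lm.laterality(_mask(data)) == ("left", False)

    def test_bilateral_with_predominance(self):
        data = np.zeros((10, 6, 6), dtype=np.uint8)
        data[:3, :4, :4] = 1  # 48 left voxels
        data[8:, :3, :4] = 1  # 24 right voxels
        assert lm.laterality(_mask(data), bilateral_min_voxels=10) == ("left", True)

    def test_exact_tie_rejected(self):
        data = np.zeros((10, 4, 4), dtype=np.uint8)
        data[0, 0, 0] = 1
        data[9, 0, 0] = 1
        with pytest.raises(ValueError, match="50/50"):
            lm.laterality(_mask(data))


class TestOverlapMap:
    def test_single_mask(self, rng):
        m = _random_mask(rng)
        count, pct = lm.overlap_map([m])
        assert np.array_equal(pct.voxels, 100.0 * m.voxels)

    def test_identical_masks_saturate(self, rng):
        m = _random_mask(rng)
        _, pct = lm.overlap_map([m] * 4)
        assert set(np.unique(pct.voxels)) <= {0.0, 100.0}

    def test_matches_per_voxel_loop_on_toy_grid(self, rng):
        masks = [_random_mask(rng, shape=(5, 5, 5), p=0.4) for _ in range(6)]
        count, _ = lm.overlap_map(masks)
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    assert count.voxels[i, j, k] == sum(
                        m.voxels[i, j, k] for m in masks
                    )

    def test_count_sum_equals_total_lesion_voxels(self, rng):
        masks = [_random_mask(rng) for _ in range(5)]
        count, _ = lm.overlap_map(masks)
        assert count.voxels.sum() == sum(m.voxels.sum() for m in masks)


class TestSubtractionMap:
    def test_equal_groups_give_zero(self, rng):
        masks = [_random_mask(rng) for _ in range(3)]
        gm = lm.subtraction_map(masks, masks)
        assert np.abs(gm.diff.voxels).max() == 0.0

    def test_bounds(self):
        on = _mask(np.ones((4, 4, 4)))
        off = _mask(np.zeros((4, 4, 4)))
        gm = lm.subtraction_map([on], [off])
        assert np.all(gm.diff.voxels == 100.0)
        assert np.all(gm.diff_display.voxels == 100.0)

    def test_swap_negates_exactly(self, rng):
        a = [_random_mask(rng) for _ in range(4)]
        b = [_random_mask(rng) for _ in range(3)]
        ab = lm.subtraction_map(a, b)
        ba = lm.subtraction_map(b, a)
        assert np.array_equal(ab.diff.voxels, -ba.diff.voxels)

    def test_display_threshold_zeroes_small_differences(self, rng):
        a = [_random_mask(rng) for _ in range(5)]
        b = [_random_mask(rng) for _ in range(5)]
        gm = lm.subtraction_map(a, b, display_threshold=20.0)
        shown = gm.diff_display.voxels
        assert np.all((shown == 0) | (np.abs(shown) > 20.0))
        # the unthresholded map is retained
        assert np.abs(gm.diff.voxels).max() >= np.abs(shown).max()


class TestCohortFrequency:
    def test_paper_style_percentages(self, toy_atlas):
        def prof(affected):
            return pd.DataFrame(
                {"affected": {"CM": affected, "CL": False}},
            ).rename_axis("nucleus")

        profiles = [prof(True)] * 23 + [prof(False)] * 5
        freq = lm.cohort_nucleus_frequency(profiles)
        assert freq.loc["CM", "n_affected"] == 23
        assert freq.loc["CM", "pct_affected"] == pytest.approx(82.1, abs=0.05)
        assert freq.loc["CL", "pct_affected"] == 0.0

    def test_four_of_five(self):
        profs = [pd.DataFrame({"affected": {"CL": i < 4}}).rename_axis("nucleus") for i in range(5)]
        freq = lm.cohort_nucleus_frequency(profs)
        assert freq.loc["CL", "pct_affected"] == pytest.approx(80.0)
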