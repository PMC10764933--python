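"""Probabilistic atlas values, mirroring, thresholding, DSI and LOO."""

import numpy as np
import pytest

from avpnorm.atlas import (
    AtlasError,
    build_atlas,
    dsi,
    flip_right_to_left,
    loo_validation,
    threshold_atlas,
)
from avpnorm.normalize import NormalizedAVP
from conftest import random_blob_grid


def _nav(grid, side="left", subject="s0"):
    return NormalizedAVP(
        grid=grid.astype(bool),
        spacing=(0.6, 0.6, 0.6),
        boundaries_mm={"iOrb": (0.0, grid.shape[1] * 0.6)},
        subject_id=subject,
        side=side,
    )


class TestFlip:
    def test_double_flip_is_identity(self, rng):
        m = _nav(random_blob_grid(rng), side="right")
        back = flip_right_to_left(flip_right_to_left(m))
        assert np.array_equal(back.grid, m.grid)

    def test_symmetric_mask_unchanged(self):
        grid = np.zeros((8, 4, 4), dtype=bool)
        grid[2:6, 1:3, 1:3] = True  # mirror-symmetric about x midplane
        m = _nav(grid, side="right")
        assert np.array_equal(flip_right_to_left(m).grid, grid)

    def test_voxel_count_conserved(self, rng):
        for _ in range(20):
            m = _nav(random_blob_grid(rng), side="right")
            assert flip_right_to_left(m).voxel_count == m.voxel_count

    def test_flipping_left_mask_warns(self):
        m = _nav(np.ones((4, 4, 4), dtype=bool), side="left")
        with pytest.warns(UserWarning, match="left"):
            flip_right_to_left(m)


class TestBuildAtlas:
    def test_identical_masks_give_zero_or_hundred(self, rng):
        grid = random_blob_grid(rng)
        atlas = build_atlas([_nav(grid), _nav(grid)], per_segment=False)
        assert set(np.unique(atlas.values)) <= {0.0, 100.0}
        assert np.array_equal(atlas.values == 100.0, grid)

    def test_half_coverage_gives_fifty_percent(self):
        grids = []
        base = np.zeros((6, 6, 6), dtype=bool)
        base[1, 1, 1] = True
        for i in range(48):
            g = base.copy() if i < 24 else np.zeros_like(base)
            g[2, 2, 2] = True  # keep every mask nonempty
            grids.append(_nav(g))
        atlas = build_atlas(grids, per_segment=False)
        assert atlas.values[1, 1, 1] == pytest.approx(50.0)
        assert threshold_atlas(atlas, 50).grid[1, 1, 1]  # inclusive boundary

    def test_values_match_exhaustive_counting(self, rng):
        masks = [_nav(random_blob_grid(rng), subject=f"s{i}") for i in range(6)]
        atlas = build_atlas(masks, per_segment=False)
        count = np.zeros(masks[0].grid.shape)
        for m in masks:
            count += m.grid
        np.testing.assert_allclose(atlas.values, count * 100.0 / 6.0, atol=1e-12)
        # support of the atlas equals the union of masks
        assert np.array_equal(atlas.values > 0, count > 0)
        # every value is a multiple of 100/6
        np.testing.assert_allclose(
            atlas.values, np.round(atlas.values / (100 / 6)) * (100 / 6), atol=1e-9
        )

    def test_empty_list_raises(self):
        with pytest.raises(AtlasError):
            build_atlas([])


class TestThreshold:
    def test_monotonically_shrinks_with_level(self, rng):
        masks = [_nav(random_blob_grid(rng)) for _ in range(5)]
        atlas = build_atlas(masks, per_segment=False)
        prev = None
        for level in (10, 30, 50, 80, 100):
            cur = threshold_atlas(atlas, level).grid
            if prev is not None:
                assert not (cur & ~prev).any()
            prev = cur

    def test_extreme_levels_are_intersection_and_union(self, rng):
        masks = [_nav(random_blob_grid(rng)) for _ in range(4)]
        atlas = build_atlas(masks, per_segment=False)
        inter = np.logical_and.reduce([m.grid for m in masks])
        union = np.logical_or.reduce([m.grid for m in masks])
        assert np.array_equal(threshold_atlas(atlas, 100).grid, inter)
        assert np.array_equal(threshold_atlas(atlas, 1e-9).grid, union)

    def test_out_of_range_level_raises(self, rng):
        atlas = build_atlas([_nav(random_blob_grid(rng))], per_segment=False)
        with pytest.raises(AtlasError):
            threshold_atlas(atlas, 0)
        with pytest.raises(AtlasError):
            threshold_atlas(atlas, 101)


class TestDSI:
    def test_identities(self, rng):
        a = random_blob_grid(rng)
        empty = np.zeros_like(a)
        assert dsi(a, a) == 1.0
        assert dsi(a, empty) == 0.0
        assert dsi(empty, empty) == 1.0

    def test_formula(self):
        a = np.zeros((10, 10, 10), dtype=bool)
        b = np.zeros_like(a)
        a.flat[:100] = True
        b.flat[40:140] = True  # overlap 60
        assert dsi(a, b) == pytest.approx(0.6)

    def test_symmetry_and_brute_force_oracle(self, rng):
        for _ in range(100):
            a = rng.random((8, 8, 8)) < 0.3
            b = rng.random((8, 8, 8)) < 0.3
            expect = (
                1.0
                if a.sum() + b.sum() == 0
                else 2 * np.sum(a & b) / (a.sum() + b.sum())
            )
            assert dsi(a, b) == pytest.approx(expect)
            assert dsi(a, b) == dsi(b, a)

    def test_grid_mismatch_raises(self):
        with pytest.raises(AtlasError):
            dsi(np.ones((2, 2, 2), dtype=bool), np.ones((3, 3, 3), dtype=bool))


class TestLOO:
    def test_identical_cohort_scores_one(self, rng):
        # mirror-symmetric grid so the right-side flip leaves it unchanged
        grid = random_blob_grid(rng)
        grid |= grid[::-1, :, :]
        by_subject = {
            f"s{i}": [_nav(grid, "left", f"s{i}"), _nav(grid, "right", f"s{i}")]
            for i in range(3)
        }
        results, summary = loo_validation(by_subject)
        assert all(r.dsi == pytest.approx(1.0) for r in results)
        assert summary["median_dsi"] == pytest.approx(1.0)

    def test_disjoint_subjects_score_zero(self):
        g1 = np.zeros((8, 8, 8), dtype=bool)
        g2 = np.zeros_like(g1)
        g1[1:3, 1:3, 1:3] = True
        g2[5:7, 5:7, 5:7] = True
        by_subject = {
            "a": [_nav(g1, "left", "a"), _nav(g1, "left", "a")],
            "b": [_nav(g2, "left", "b"), _nav(g2, "left", "b")],
        }
        results, summary = loo_validation(by_subject)
        assert all(r.dsi == 0.0 for r in results)

    def test_single_subject_raises(self, rng):
        with pytest.raises(AtlasError):
            loo_validation({"a": [_nav(random_blob_grid(rng))]})
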