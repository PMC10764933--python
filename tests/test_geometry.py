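"""Centroids, path lengths, cross-sectional shape and segment biometrics."""

import numpy as np
import pytest

from avpnorm.geometry import (
    GeometryError,
    centroid_path,
    segment_biometrics,
    slice_centroid,
    slice_csa,
    slice_shape,
)
from avpnorm.mask_io import LabeledMask


def _digitized_ellipse(h1, h2, spacing=0.6, offset=(0.17, 0.29), n=40, theta=0.0):
    xs = (np.arange(n) - n / 2) * spacing
    gx, gz = np.meshgrid(xs, xs, indexing="ij")
    dx, dz = gx - offset[0], gz - offset[1]
    ct, st = np.cos(theta), np.sin(theta)
    return ((dx * ct + dz * st) / h1) ** 2 + ((-dx * st + dz * ct) / h2) ** 2 <= 1


class TestSliceCentroid:
    def test_single_voxel(self):
        sl = np.zeros((8, 8), dtype=bool)
        sl[3, 5] = True
        assert slice_centroid(sl, (0.6, 0.6)) == pytest.approx((1.8, 3.0))

    def test_symmetric_block(self):
        sl = np.zeros((8, 8), dtype=bool)
        sl[2:4, 4:6] = True
        assert slice_centroid(sl, (1.0, 1.0)) == pytest.approx((2.5, 4.5))

    def test_matches_brute_force_mean(self, rng):
        sl = np.zeros((20, 20), dtype=bool)
        idx = rng.choice(400, size=50, replace=False)
        sl.flat[idx] = True
        cx, cz = slice_centroid(sl, (0.6, 0.6))
        coords = np.argwhere(sl) * 0.6
        assert (cx, cz) == pytest.approx((coords[:, 0].mean(), coords[:, 1].mean()))

    def test_empty_slice_raises(self):
        with pytest.raises(GeometryError):
            slice_centroid(np.zeros((4, 4), dtype=bool), (0.6, 0.6))


class TestCentroidPath:
    def _mask_from_slices(self, slices, spacing=(0.6, 0.6, 0.6)):
        grid = np.stack(slices, axis=1)
        return LabeledMask(grid, spacing, "iOrb", "left", "t")

    def test_coaxial_discs_have_axial_length(self):
        sl = np.zeros((9, 9), dtype=bool)
        sl[3:6, 3:6] = True
        path = centroid_path(self._mask_from_slices([sl] * 5))
        assert path.tl_mm == pytest.approx(2.4)
        assert len(path.distances_mm) == 4
        np.testing.assert_allclose(path.distances_mm, 0.6)

    def test_three_four_five_drift(self):
        # centroid drifts 0.8 mm in-plane per 0.6 mm axial step -> D = 1.0
        slices = []
        for i in range(4):
            sl = np.zeros((12, 12), dtype=bool)
            sl[2 + i * 2, 3:5] = True  # 2 voxels, x centroid steps 1.2 mm?
            slices.append(sl)
        # use spacing where in-plane step is 0.8: x step 2 voxels * 0.4 mm
        mask = self._mask_from_slices(slices, spacing=(0.4, 0.6, 0.4))
        path = centroid_path(mask)
        np.testing.assert_allclose(path.distances_mm, 1.0)
        assert path.tl_mm == pytest.approx(3.0)

    def test_sinusoidal_centerline_matches_polyline_oracle(self):
        n = 30
        xs = np.round(8 + 3 * np.sin(np.linspace(0, 2 * np.pi, n))).astype(int)
        slices = []
        for x in xs:
            sl = np.zeros((16, 16), dtype=bool)
            sl[x, 7] = True
            slices.append(sl)
        path = centroid_path(self._mask_from_slices(slices))
        pts = np.column_stack([xs * 0.6, np.arange(n) * 0.6, np.full(n, 7 * 0.6)])
        oracle = np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1)).sum()
        assert path.tl_mm == pytest.approx(oracle)

    def test_tl_invariant_under_inplane_translation(self, default_phantom):
        mask = default_phantom[0].masks["iCran"]
        shifted = LabeledMask(
            np.roll(mask.grid, (3, -2), axis=(0, 2)), mask.spacing, "iCran", "left", "t"
        )
        assert centroid_path(shifted).tl_mm == pytest.approx(centroid_path(mask).tl_mm)

    def test_noncontiguous_mask_raises(self):
        sl = np.zeros((6, 6), dtype=bool)
        sl[2, 2] = True
        empty = np.zeros((6, 6), dtype=bool)
        with pytest.raises(GeometryError, match="contiguous"):
            centroid_path(self._mask_from_slices([sl, empty, sl]))


class TestSliceShape:
    def test_digitized_circle_is_nearly_circular(self):
        sl = _digitized_ellipse(3.0, 3.0)
        assert slice_shape(sl, (0.6, 0.6)).epsilon <= 0.05

    @pytest.mark.parametrize("theta", [0.0, 0.5])
    def test_digitized_ellipse_recovers_ellipticity(self, theta):
        # digitized on a fine sub-grid, where the moment estimate converges
        sl = _digitized_ellipse(3.0, 1.5, spacing=0.15, n=80, theta=theta)
        shape = slice_shape(sl, (0.15, 0.15))
        assert shape.epsilon == pytest.approx(0.5, abs=0.05)
        assert shape.h1 >= shape.h2 > 0

    def test_csa_is_voxel_count_times_pixel_area(self, rng):
        sl = np.zeros((10, 10), dtype=bool)
        sl.flat[rng.choice(100, size=10, replace=False)] = True
        assert slice_csa(sl, (0.6, 0.6)) == pytest.approx(3.6)

    def test_single_voxel_epsilon_zero(self):
        sl = np.zeros((5, 5), dtype=bool)
        sl[2, 2] = True
        assert slice_shape(sl, (0.6, 0.6)).epsilon == pytest.approx(0.0)

    def test_collinear_slice_epsilon_below_one(self):
        sl = np.zeros((9, 9), dtype=bool)
        sl[2:7, 4] = True
        eps = slice_shape(sl, (0.6, 0.6)).epsilon
        assert 0.0 < eps < 1.0

    def test_epsilon_scale_invariant(self):
        # scaling the whole geometry (shape and pixel size) by any factor
        # leaves the dimensionless ellipticity unchanged
        small = slice_shape(
            _digitized_ellipse(2.0, 1.0, spacing=0.4, offset=(0.1, 0.2)), (0.4, 0.4)
        ).epsilon
        large = slice_shape(
            _digitized_ellipse(6.0, 3.0, spacing=1.2, offset=(0.3, 0.6)), (1.2, 1.2)
        ).epsilon
        assert small == pytest.approx(large, abs=1e-12)


class TestSegmentBiometrics:
    def test_volume_is_voxel_count_times_voxel_volume(self):
        grid = np.zeros((12, 10, 12), dtype=bool)
        grid[1:11, :, 1:11] = True  # 100 voxels x 10 slices
        mask = LabeledMask(grid, (0.6, 0.6, 0.6), "iOrb", "left", "t")
        rec = segment_biometrics(mask)
        assert rec.volume_mm3 == pytest.approx(1000 * 0.216)
        assert rec.mcsa_mm2 == pytest.approx(rec.volume_mm3 / rec.length_mm)

    def test_cylinder_biometrics_match_analytic_truth(self, cylinder30):
        segment_set, truth = cylinder30
        union = LabeledMask(
            segment_set.union_grid(), (0.6, 0.6, 0.6), "wholeAVP", "left", "cyl"
        )
        rec = segment_biometrics(union)
        whole = truth[truth.segment == "wholeAVP"].iloc[0]
        assert rec.volume_mm3 == pytest.approx(whole.volume_mm3, rel=0.03)
        assert rec.length_mm == pytest.approx(30.0, abs=0.6)
        assert rec.mcsa_mm2 == pytest.approx(np.pi * 1.5**2, rel=0.03)
        assert rec.epsilon <= 0.06  # circular cross-section

    def test_single_slice_segment_signals_zero_length(self):
        grid = np.zeros((8, 4, 8), dtype=bool)
        grid[2:5, 1, 2:5] = True
        mask = LabeledMask(grid, (0.6, 0.6, 0.6), "OC", "left", "t")
        with pytest.raises(GeometryError, match="single-slice"):
            segment_biometrics(mask)
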