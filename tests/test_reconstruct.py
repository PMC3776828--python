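"""Voxel carving, the likelihood index, and the adaptive volume threshold."""

import numpy as np
import pytest

from voxmouse import scene
from voxmouse.errors import ConfigurationError
from voxmouse.reconstruct import (
    BodyVolume,
    VolumeStats,
    VoxelGrid,
    carve,
    estimate_volume_stats,
    likelihood_index,
    threshold_volume,
)
from voxmouse.silhouette import BoundingCube


def sphere_shape(r=20.0, center=(0.0, 0.0, 40.0)):
    return scene.MouseShape(
        body=(scene.Ellipsoid(np.array(center), np.full(3, r), np.eye(3)),),
        tail_spheres=(),
        present_tail=False,
    )


@pytest.fixture(scope="module")
def sphere_carve(rig):
    shape = sphere_shape()
    masks = [scene.exact_mask(shape, cam) for cam in rig]
    grid = VoxelGrid.from_cube(BoundingCube((0, 0, 40.0), 40.0), edge=2.0)
    C = carve(masks, rig, grid)
    return shape, masks, grid, C


class TestCarve:
    def test_sphere_full_correspondence_blob(self, rig, sphere_carve):
        shape, masks, grid, C = sphere_carve
        full = C == rig.n
        vol = full.sum() * 8.0
        analytic = 4.0 / 3.0 * np.pi * 20.0**3
        assert 0.9 * analytic <= vol <= 1.5 * analytic
        centroid = grid.centers()[full.ravel()].mean(axis=0)
        assert np.all(np.abs(centroid - (0, 0, 40.0)) < 1.0)

    def test_interior_voxels_reach_full_correspondence(self, rig, sphere_carve):
        """Voxels well inside the true shape are seen by every camera."""
        shape, masks, grid, C = sphere_carve
        centers = grid.centers()
        deep = np.linalg.norm(centers - np.array([0, 0, 40.0]), axis=1) < 20.0 - 3.0
        assert np.all(C.ravel()[deep] == rig.n)

    def test_empty_masks_give_zero_counts(self, rig):
        grid = VoxelGrid.from_cube(BoundingCube((0, 0, 40.0), 20.0), edge=4.0)
        masks = [np.zeros((c.image_size[1], c.image_size[0]), bool) for c in rig]
        assert carve(masks, rig, grid).max() == 0

    def test_one_camera_emptied_caps_counts(self, rig, sphere_carve):
        shape, masks, grid, _ = sphere_carve
        masks2 = list(masks)
        masks2[0] = np.zeros_like(masks2[0])
        with pytest.warns(UserWarning):
            C = carve(masks2, rig, grid)
        assert C.max() == rig.n - 1

    def test_mask_count_mismatch(self, rig):
        grid = VoxelGrid.from_cube(BoundingCube((0, 0, 0), 10.0), edge=2.0)
        with pytest.raises(ConfigurationError):
            carve([np.zeros((4, 4), bool)], rig, grid)


class TestVoxelGrid:
    def test_center_formula(self):
        g = VoxelGrid(origin=(0.0, 0.0, 0.0), edge=2.0, dims=(2, 2, 2))
        c = g.centers()
        assert np.allclose(c[0], (1.0, 1.0, 1.0))
        assert np.allclose(c[-1], (3.0, 3.0, 3.0))

    def test_z_clip(self):
        g = VoxelGrid.from_cube(BoundingCube((0, 0, 50.0), 100.0), edge=2.0, z_range=(0, 120))
        zs = g.centers()[:, 2]
        assert zs.min() > 0 and zs.max() < 120

    def test_invalid(self):
        with pytest.raises(ConfigurationError):
            VoxelGrid(origin=(0, 0, 0), edge=-1.0, dims=(2, 2, 2))


class TestLikelihoodIndex:
    def test_uniform_interior(self):
        C = np.full((5, 5, 5), 10.0)
        L = likelihood_index(C)
        assert L[2, 2, 2] == pytest.approx(20.0)

    def test_isolated_voxel(self):
        C = np.zeros((5, 5, 5))
        C[2, 2, 2] = 10.0
        L = likelihood_index(C)
        assert L[2, 2, 2] == pytest.approx(10.0)

    def test_monotone_in_neighbor_support(self):
        C = np.zeros((5, 5, 7))
        C[2, 2, 2] = 8.0
        C[2, 2, 4] = 8.0
        C[2, 2, 5] = 8.0  # voxel at (2,2,4) has one supporting neighbour
        L = likelihood_index(C)
        assert L[2, 2, 4] > L[2, 2, 2]

    def test_range_bound(self):
        rng = np.random.default_rng(0)
        C = rng.integers(0, 11, size=(6, 6, 6)).astype(float)
        L = likelihood_index(C)
        assert np.all(L <= 2 * 10.0 + 1e-9)
        assert np.all(L >= C)


class TestThresholdVolume:
    def _grid(self, n=8, edge=2.0):
        return VoxelGrid(origin=(0, 0, 0), edge=edge, dims=(n, n, n))

    def test_stops_inside_band(self):
        grid = self._grid()
        L = np.zeros(grid.dims)
        L[:4, :4, :4] = 18.0  # 64 voxels = 512 mm^3
        L[4:, :4, :4] = 12.0  # +64 more at a weaker threshold
        stats = VolumeStats(mu=512.0, sigma=20.0)
        body = threshold_volume(L, stats, grid)
        lo, hi = stats.band()
        assert lo <= body.volume <= hi
        assert body.threshold == pytest.approx(18.0)

    def test_huge_sigma_keeps_strictest_threshold(self):
        grid = self._grid()
        L = np.zeros(grid.dims)
        L[0, 0, 0] = 20.0
        L[1:3, :2, :2] = 10.0
        stats = VolumeStats(mu=100.0, sigma=1e6)
        body = threshold_volume(L, stats, grid)
        assert body.threshold == pytest.approx(20.0)
        assert body.count == 1

    def test_band_skipped_returns_closest_to_mu(self):
        grid = self._grid()
        L = np.zeros(grid.dims)
        L[:2, :2, :2] = 20.0  # 8 voxels = 64 mm^3
        L[2:6, :4, :4] = 10.0  # 136 voxels total = 1088 mm^3
        stats = VolumeStats(mu=200.0, sigma=10.0)  # band [170, 230]: skipped over
        body = threshold_volume(L, stats, grid)
        assert body.volume == pytest.approx(64.0)  # closest to mu among {64, 1088}

    def test_superlevel_sets_nested(self):
        rng = np.random.default_rng(3)
        grid = self._grid()
        L = rng.random(grid.dims) * 20.0
        taus = np.sort(np.unique(L.ravel()))[::-1][:20]
        prev = None
        for tau in taus:
            sel = set(map(tuple, np.argwhere(L >= tau)))
            if prev is not None:
                assert prev <= sel
            prev = sel

    def test_empty_field(self):
        body = threshold_volume(np.zeros((4, 4, 4)), VolumeStats(100, 10), self._grid(4))
        assert body.count == 0


class TestVolumeStats:
    def test_constant_volumes_hit_sigma_floor(self):
        s = estimate_volume_stats([10000.0] * 50)
        assert s.mu == pytest.approx(10000.0)
        assert s.sigma == pytest.approx(100.0)  # 1% floor

    def test_outlier_frame_ignored(self):
        vols = [9800.0] * 49 + [30000.0]
        s = estimate_volume_stats(vols)
        assert s.mu == pytest.approx(9800.0)
        assert s.sigma < 1000.0

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        vols = rng.normal(10000, 300, 40)
        a = estimate_volume_stats(vols)
        b = estimate_volume_stats(rng.permutation(vols))
        assert a.mu == b.mu and a.sigma == b.sigma

    def test_few_frames_fall_back_to_prior(self):
        prior = VolumeStats(12345.0, 200.0)
        assert estimate_volume_stats([1.0] * 5, prior=prior) is prior
        with pytest.raises(ConfigurationError):
            estimate_volume_stats([1.0] * 5)


class TestResolutionConvergence:
    def test_hull_volume_decreases_toward_truth_with_finer_voxels(self, rig):
        """With exact masks the carved volume approaches the true sphere
        volume from above as the voxel edge shrinks (4 -> 2 -> 1 mm)."""
        shape = sphere_shape()
        masks = [scene.exact_mask(shape, cam) for cam in rig]
        analytic = 4.0 / 3.0 * np.pi * 20.0**3
        vols = []
        for edge in (4.0, 2.0, 1.0):
            grid = VoxelGrid.from_cube(BoundingCube((0, 0, 40.0), 32.0), edge=edge)
            C = carve(masks, rig, grid)
            vols.append(np.count_nonzero(C == rig.n) * edge**3)
        errs = [abs(v - analytic) / analytic for v in vols]
        # voxel-edge quantisation shrinks with resolution; the finest grid
        # reproduces the analytic volume to ~2%
        assert errs[2] <= errs[0] + 0.01
        assert errs[2] < 0.02
        assert all(0.9 * analytic <= v <= 1.5 * analytic for v in vols)
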