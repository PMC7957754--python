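import numpy as np
import pytest

from swvm import (
    Frame,
    MaskVolume,
    VoxelGrid,
    finalize_voxel,
    mean_2d_swv,
    reconstruct,
    weighted_mean_swv,
)
from swvm.geometry import interpolate_pose, map_frame_to_world
from swvm.reconstruction import EmptyReconstructionError, ReconstructionError

from conftest import make_moving_sweep, make_static_sweep


def brute_force_grid(sweep, spacing):
    """Definitional oracle: per-voxel sample lists, sequential statistics."""
    pts_all, vals_all = [], []
    for frame in sweep.frames_of("swe"):
        pose = interpolate_pose(sweep.poses, frame.t)
        pts, vals = map_frame_to_world(frame, pose, sweep.calibration)
        pts_all.append(pts)
        vals_all.append(vals)
    pts = np.concatenate(pts_all)
    vals = np.concatenate(vals_all)
    idx_min = np.floor(pts.min(axis=0) / spacing).astype(int) - 1
    buckets: dict[tuple, list] = {}
    for p, v in zip(pts, vals):
        key = tuple(int(np.floor(c / spacing)) - m for c, m in zip(p, idx_min))
        buckets.setdefault(key, []).append(v)
    stats = {}
    for key, xs in buckets.items():
        acc = 0.0
        for x in xs:
            acc += x
        mean = acc / len(xs)
        ssq = 0.0
        for x in xs:
            ssq += (x - mean) ** 2
        sigma = np.sqrt(ssq / (len(xs) - 1)) if len(xs) > 1 else 0.0
        stats[key] = (mean, sigma, len(xs))
    return stats


class TestFinalizeVoxel:
    @pytest.mark.parametrize(
        "samples, v, sigma, n, omega",
        [
            ([2, 2, 2], 2.0, 0.0, 3, 6.0),  # sigma floored at 0.5
            ([3.0], 3.0, 0.0, 1, 2.0),  # single sample regularised by the floor
            ([1, 3], 2.0, np.sqrt(2), 2, 2 / np.sqrt(2)),
        ],
    )
    def test_hand_computed_examples(self, samples, v, sigma, n, omega):
        got = finalize_voxel(samples)
        assert got[0] == pytest.approx(v)
        assert got[1] == pytest.approx(sigma)
        assert got[2] == n
        assert got[3] == pytest.approx(omega)

    def test_empty_voxel_rejected(self):
        with pytest.raises(ReconstructionError):
            finalize_voxel([])

    def test_weight_bounded_by_twice_count(self, rng):
        for _ in range(20):
            xs = rng.normal(2.0, rng.uniform(0, 2), size=rng.integers(1, 30))
            xs = np.abs(xs) + 0.01
            v, sigma, n, omega = finalize_voxel(xs)
            assert omega <= 2 * n + 1e-12


def grid_from_voxels(voxels):
    """Build a finalized 1-row grid from (mean, sigma, n) triples."""
    k = len(voxels)
    mean = np.array([v[0] for v in voxels]).reshape(k, 1, 1)
    sigma = np.array([v[1] for v in voxels]).reshape(k, 1, 1)
    count = np.array([v[2] for v in voxels]).reshape(k, 1, 1)
    return VoxelGrid(
        origin=np.zeros(3), spacing=0.5, dims=(k, 1, 1),
        count=count, mean=mean, sigma=sigma,
    )


class TestWeightedMean:
    def test_single_voxel_weights_cancel(self):
        grid = grid_from_voxels([(2.0, 0.3, 5)])
        assert weighted_mean_swv(grid) == pytest.approx(2.0)

    def test_hand_computed_two_voxels(self):
        # A: n=4 sigma=0.5 -> w=8; B: n=2 sigma=1.0 -> w=2
        grid = grid_from_voxels([(1.0, 0.5, 4), (2.0, 1.0, 2)])
        assert weighted_mean_swv(grid) == pytest.approx(1.2)

    def test_sigma_floor_equalises_weights(self):
        # sigma 0.2 floored to 0.5 -> both weights 10
        grid = grid_from_voxels([(3.0, 0.2, 5), (1.0, 0.5, 5)])
        assert weighted_mean_swv(grid) == pytest.approx(2.0)

    def test_inverse_se_scheme(self):
        # sqrt(n)/sigma: A -> 2/0.5=4, B -> sqrt(4)/1=2
        grid = grid_from_voxels([(1.0, 0.5, 4), (2.0, 1.0, 4)])
        assert weighted_mean_swv(grid, weight_scheme="inverse_se") == pytest.approx(
            (4 * 1.0 + 2 * 2.0) / 6.0
        )

    def test_empty_segmentation_rejected(self):
        grid = grid_from_voxels([(2.0, 0.3, 5)])
        mask = MaskVolume(grid.origin, grid.spacing, np.zeros(grid.dims, dtype=bool))
        with pytest.raises(EmptyReconstructionError):
            weighted_mean_swv(grid, mask)


class TestReconstruct:
    def test_matches_brute_force_oracle_exactly(self, rng):
        px = [rng.uniform(1, 3, (10, 10)) for _ in range(3)]
        sweep = make_moving_sweep(px, step_mm=0.7, spacing=(0.9, 1.1))
        grid = reconstruct(sweep, spacing=0.5)
        oracle = brute_force_grid(sweep, 0.5)
        assert int(grid.count.sum()) == sum(n for _, _, n in oracle.values())
        for key, (mean, sigma, n) in oracle.items():
            assert grid.count[key] == n
            assert grid.mean[key] == mean  # bitwise: same summation order
            assert grid.sigma[key] == sigma
        assert int((grid.count > 0).sum()) == len(oracle)

    def test_single_frame_coarse_pixels_land_in_own_voxels(self):
        sweep = make_static_sweep([np.full((3, 3), 2.0)], spacing=(2.0, 2.0))
        grid = reconstruct(sweep, spacing=0.5)
        assert int(grid.count.sum()) == 9
        assert int((grid.count == 1).sum()) == 9

    def test_uniform_field_zero_noise(self):
        sweep = make_moving_sweep([np.full((6, 6), 2.5)] * 4, step_mm=0.5)
        grid = reconstruct(sweep, spacing=0.5)
        assert np.all(grid.mean[grid.nonempty] == 2.5)
        assert np.all(grid.sigma[grid.nonempty] == 0.0)

    def test_zero_pixels_discarded_means_unchanged(self, rng):
        px = [rng.uniform(1, 3, (6, 6)) for _ in range(2)]
        sweep = make_moving_sweep(px, step_mm=0.5)
        grid = reconstruct(sweep, spacing=0.5)
        # zero out 30% of pixels: identical means, smaller counts
        px_drop = [p.copy() for p in px]
        drop = rng.random(px_drop[0].shape) < 0.3
        px_drop[0][drop] = 0.0
        grid_drop = reconstruct(make_moving_sweep(px_drop, step_mm=0.5), spacing=0.5)
        assert int(grid_drop.count.sum()) == int(grid.count.sum()) - int(drop.sum())

    def test_appending_zero_frames_is_bit_identical(self, rng):
        px = [rng.uniform(1, 3, (6, 6)) for _ in range(2)]
        base = reconstruct(make_moving_sweep(px, step_mm=0.5), spacing=0.5)
        withz = reconstruct(
            make_moving_sweep(px + [np.zeros((6, 6))], step_mm=0.5), spacing=0.5
        )
        assert np.array_equal(base.mean, withz.mean)
        assert np.array_equal(base.sigma, withz.sigma)
        assert np.array_equal(base.count, withz.count)
        assert np.array_equal(base.origin, withz.origin)

    def test_conservation_of_valid_samples(self, rng):
        px = [rng.uniform(0.5, 3, (7, 5)) for _ in range(3)]
        px[1][2, 2] = 0.0
        sweep = make_moving_sweep(px, step_mm=0.6)
        grid = reconstruct(sweep, spacing=0.5)
        n_valid = sum(int(np.count_nonzero(p)) for p in px)
        assert int(grid.count.sum()) == n_valid

    def test_frame_order_invariance(self, rng):
        px = [rng.uniform(1, 3, (6, 6)) for _ in range(4)]
        sweep = make_moving_sweep(px, step_mm=0.5)
        grid = reconstruct(sweep, spacing=0.5)
        # reverse frame order but keep each frame's pose by reversing both
        rev = make_moving_sweep(px[::-1], step_mm=-0.5)
        # shift rev origin: frame i now at z = -0.5*i; same world layout reversed
        grid_rev = reconstruct(rev, spacing=0.5)
        means = np.sort(grid.mean[grid.nonempty])
        means_rev = np.sort(grid_rev.mean[grid_rev.nonempty])
        assert np.max(np.abs(means - means_rev)) <= 1e-9

    def test_empty_sweep_raises(self):
        sweep = make_static_sweep([np.zeros((4, 4))])
        with pytest.raises(EmptyReconstructionError):
            reconstruct(sweep, spacing=0.5)

    def test_frames_outside_pose_span_are_skipped(self, caplog):
        import logging

        px = [np.full((4, 4), 2.0), np.full((4, 4), 3.0)]
        frames_sweep = make_static_sweep(px, t_step=10.0)  # second frame at t=10
        # pose span only covers [0, 11]; shrink to [0, 5] to strand frame 2
        frames_sweep.poses = frames_sweep.poses[:1] + [
            type(frames_sweep.poses[0])(5.0, frames_sweep.poses[0].transform)
        ]
        with caplog.at_level(logging.WARNING):
            grid = reconstruct(frames_sweep, spacing=0.5)
        assert int(grid.count.sum()) == 16  # only the first frame binned
        assert any("skipped" in r.message for r in caplog.records)

    def test_unbiased_on_noisy_uniform_field(self, rng):
        v0, sd = 2.0, 0.2
        px = [np.abs(rng.normal(v0, sd, (20, 20))) for _ in range(5)]
        sweep = make_moving_sweep(px, step_mm=0.5)
        grid = reconstruct(sweep, spacing=0.5)
        n = int(grid.count.sum())
        assert abs(weighted_mean_swv(grid) - v0) <= 3 * sd / np.sqrt(n)

    def test_grid_origin_snapped_to_spacing(self, rng):
        px = [rng.uniform(1, 2, (5, 5))]
        sweep = make_static_sweep(px, spacing=(0.73, 1.31))
        grid = reconstruct(sweep, spacing=0.5)
        assert np.allclose(grid.origin / 0.5, np.round(grid.origin / 0.5))


class TestMean2D:
    def test_constant_roi(self):
        f = Frame(0.0, np.full((4, 4), 2.0), (1.0, 1.0))
        assert mean_2d_swv([f]) == pytest.approx(2.0)

    def test_pooled_mean_across_frames(self):
        frames = [
            Frame(0.0, np.full((3, 3), 1.0), (1.0, 1.0)),
            Frame(1.0, np.full((3, 3), 3.0), (1.0, 1.0)),
        ]
        assert mean_2d_swv(frames) == pytest.approx(2.0)

    def test_zero_discard_changes_denominator(self):
        f = Frame(0.0, np.array([[2.0, 2.0], [0.0, 4.0]]), (1.0, 1.0))
        assert mean_2d_swv([f]) == pytest.approx(8.0 / 3.0)
        assert mean_2d_swv([f], discard_zeros=False) == pytest.approx(2.0)

    def test_roi_mask_applied(self):
        f = Frame(0.0, np.array([[1.0, 9.0], [9.0, 9.0]]), (1.0, 1.0))
        roi = np.array([[True, False], [False, False]])
        assert mean_2d_swv([f], [roi]) == pytest.approx(1.0)

    def test_empty_roi_rejected(self):
        f = Frame(0.0, np.zeros((2, 2)), (1.0, 1.0))
        with pytest.raises(EmptyReconstructionError):
            mean_2d_swv([f])
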