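import numpy as np
import pytest

from canopy_complexity.canopy_entropy import (
    CanopyEntropy,
    _kde_on_grid,
    canopy_entropy,
    correct_sdb,
    layer_profile,
    plane_entropy,
    voxel_center_resample,
)
from canopy_complexity.errors import InsufficientPointsError
from canopy_complexity.io import PointCloud
from canopy_complexity.synthetic import (
    generate_biased_canopy,
    generate_uniform_cube,
    generate_uniform_slab,
)
from canopy_complexity.trend import mk_trend_test

from _oracles import brute_layer_nn_means, brute_plane_entropy


class TestLayerProfile:
    def test_two_points_one_layer(self):
        cloud = PointCloud([[0, 0, 0.2], [1, 0, 0.4]])
        prof = layer_profile(cloud, layer_width=1.0)
        assert len(prof.layer_floors) == 1
        assert prof.mean_nn_distance[0] == pytest.approx(np.sqrt(1.0 + 0.04))

    def test_regular_lattice_mean_spacing(self):
        ticks = np.arange(0, 5.0, 0.1)
        xx, yy = np.meshgrid(ticks, ticks, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, 0.5)])
        prof = layer_profile(PointCloud(pts), layer_width=1.0)
        assert prof.mean_nn_distance[0] == pytest.approx(0.1, rel=0.02)

    def test_matches_all_pairs_oracle(self, rng):
        pts = rng.uniform(0, 8, size=(2000, 3))
        prof = layer_profile(PointCloud(pts), layer_width=1.0)
        expected = brute_layer_nn_means(pts, 1.0)
        assert np.allclose(prof.mean_nn_distance, expected, atol=1e-9, equal_nan=True)

    def test_sparse_layers_carry_no_distance(self):
        pts = [[0, 0, 0.5], [1, 0, 0.5], [0, 0, 5.5]]  # middle layers empty
        prof = layer_profile(PointCloud(pts), layer_width=1.0)
        assert np.isnan(prof.mean_nn_distance[-1])  # single-point layer
        assert len(prof.distance_sequence) == 1

    def test_single_point_raises(self):
        with pytest.raises(InsufficientPointsError):
            layer_profile(PointCloud([[0, 0, 0]]))


class TestVoxelCenterResample:
    def test_single_occupied_voxel(self):
        cloud = PointCloud([[0.1, 0.1, 0.1], [0.2, 0.2, 0.2]])
        out = voxel_center_resample(cloud, 1.0)
        assert np.allclose(out.points, [[0.6, 0.6, 0.6]])

    def test_cube_corners_keep_eight_centers(self):
        corners = np.array(
            [[i, j, k] for i in (0, 4.0) for j in (0, 4.0) for k in (0, 4.0)]
        )
        out = voxel_center_resample(PointCloud(corners), 2.0)
        assert len(out) == 8

    def test_matches_brute_voxel_scan(self, rng):
        pts = rng.uniform(0, 7, size=(3000, 3))
        v = 0.9
        out = voxel_center_resample(PointCloud(pts), v)
        origin = pts.min(axis=0)
        expected = set()
        for p in pts:
            idx = tuple(
                min(int((p[d] - origin[d]) // v), int((pts[:, d].max() - origin[d]) // v))
                for d in range(3)
            )
            expected.add(idx)
        got = {
            tuple(np.round((q - origin) / v - 0.5).astype(int)) for q in out.points
        }
        assert got == expected

    def test_output_never_larger_and_separated(self, rng):
        pts = rng.uniform(0, 5, size=(4000, 3))
        out = voxel_center_resample(PointCloud(pts), 0.5).points
        assert len(out) <= len(pts)
        # distinct voxel centers differ by >= voxel size along some axis
        diff = np.abs(out[:, None, :] - out[None, :, :]).max(axis=2)
        np.fill_diagonal(diff, np.inf)
        assert diff.min() >= 0.5 * (1 - 1e-9)


class TestCorrectSDB:
    def test_uniform_cube_left_unchanged(self):
        cloud = generate_uniform_cube(15.0, 10_000, seed=42)
        out, report = correct_sdb(cloud)
        assert not report.biased_initially
        assert report.final_voxel_size is None
        assert np.array_equal(out.points, cloud.points)

    def test_biased_canopy_flagged_and_detrended(self):
        cloud = generate_biased_canopy(
            density_decay=0.3, height=20.0, n_points=200_000, seed=7
        )
        out, report = correct_sdb(cloud)
        assert report.biased_initially
        assert report.iterations >= 1
        assert len(report.voxel_sizes) == report.iterations
        assert all(b > a for a, b in zip(report.voxel_sizes, report.voxel_sizes[1:]))
        final_seq = layer_profile(out).distance_sequence
        final_test = mk_trend_test(final_seq)
        assert not final_test.trend_detected
        # the correction reduces the strength of the height trend
        assert abs(final_test.z_score) < abs(report.tests[0].z_score)

    def test_few_layers_returned_unchanged(self):
        # 3 usable layers: MK test not applicable
        cloud = generate_uniform_slab(10.0, 3.0, 3000, seed=0)
        out, report = correct_sdb(cloud)
        assert not report.biased_initially
        assert len(out) == len(cloud)


class TestPlaneEntropy:
    def test_single_gaussian_closed_form(self):
        h = 0.2
        assert plane_entropy([[0.0, 0.0]], bandwidth=h) == pytest.approx(
            np.log(2 * np.pi * np.e * h * h), abs=1e-3
        )

    def test_uniform_square_analytic_limit(self, rng):
        pts = rng.uniform(0, 15, size=(10_000, 2))
        assert plane_entropy(pts) == pytest.approx(np.log(225.0), rel=0.02)

    def test_grid_refinement_stable(self, rng):
        pts = rng.uniform(0, 15, size=(2000, 2))
        coarse = plane_entropy(pts, grid_step=0.1)
        fine = plane_entropy(pts, grid_step=0.05)
        assert abs(coarse - fine) < 1e-3

    def test_matches_per_point_accumulation_oracle(self, rng):
        pts = rng.uniform(0, 3, size=(200, 2))
        ours = plane_entropy(pts, bandwidth=0.2, grid_step=0.1)
        brute = brute_plane_entropy(pts, 0.2, 0.1)
        assert ours == pytest.approx(brute, abs=1e-9)

    def test_normalization_factor_close_to_one(self, rng):
        pts = rng.uniform(0, 10, size=(5000, 2))
        density, cell_area = _kde_on_grid(pts, 0.2, 0.1)
        assert density.sum() * cell_area == pytest.approx(1.0, abs=0.01)

    def test_grid_step_must_not_exceed_bandwidth(self):
        with pytest.raises(ValueError):
            plane_entropy([[0.0, 0.0]], bandwidth=0.2, grid_step=0.3)


class TestCanopyEntropy:
    def test_pythagorean_combination(self):
        res = canopy_entropy(generate_uniform_cube(8.0, 3000, seed=5))
        assert res.ce == pytest.approx(
            np.sqrt(res.ce_xy ** 2 + res.ce_xz ** 2 + res.ce_yz ** 2)
        )
        assert res.ce >= abs(res.ce_xy)

    def test_dense_cube_analytic_limit(self):
        res = canopy_entropy(generate_uniform_cube(15.0, 30_000, seed=3))
        target = np.sqrt(3) * np.log(225.0)
        assert res.ce == pytest.approx(target, rel=0.02)
        for comp in (res.ce_xy, res.ce_xz, res.ce_yz):
            assert comp == pytest.approx(np.log(225.0), rel=0.02)

    def test_translation_invariance(self):
        cloud = generate_uniform_cube(8.0, 4000, seed=9)
        shifted = PointCloud(cloud.points + np.array([120.0, -40.0, 7.0]))
        a = canopy_entropy(cloud)
        b = canopy_entropy(shifted)
        assert b.ce == pytest.approx(a.ce, abs=1e-9)

    def test_scaling_shifts_entropy_by_two_log_two(self):
        cloud = generate_uniform_cube(6.0, 3000, seed=11)
        base = CanopyEntropy(correct_bias=False).fit(cloud.points)
        doubled = CanopyEntropy(
            bandwidth=0.4, grid_step=0.2, correct_bias=False
        ).fit(cloud.points * 2.0)
        assert doubled.entropy_xy_ - base.entropy_xy_ == pytest.approx(
            2 * np.log(2), abs=1e-6
        )

    def test_plot_size_monotonicity(self):
        ces = [
            canopy_entropy(generate_uniform_cube(side, 8000, seed=2)).ce
            for side in (8.0, 12.0, 16.0)
        ]
        assert ces[0] < ces[1] < ces[2]

    def test_estimator_interface(self):
        est = CanopyEntropy(bandwidth=0.25)
        assert est.get_params()["bandwidth"] == 0.25
        est.fit(generate_uniform_cube(6.0, 2000, seed=1).points)
        assert est.entropy_ > 0
        assert est.n_points_used_ > 0
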