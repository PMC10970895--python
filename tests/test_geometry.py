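"""Homography estimation (DLT, RANSAC), matching, warping and morphology."""

import numpy as np
import pytest

from msreg.geometry import (
    DegenerateConfigurationError,
    Homography,
    KeypointSet,
    MatchSet,
    RansacParams,
    SiftParams,
    detect_keypoints,
    dilate,
    erode,
    estimate_homography_dlt,
    estimate_homography_ransac,
    match_descriptors,
    ratio_filter,
    warp_image,
    warp_mask,
    warp_polygon,
)
from msreg.scene_io import Band, PolygonRegion, rasterize


def random_bounded_homography(rng, shape=(960, 1280), magnitude=20.0):
    """Perspective map with corner displacements bounded by `magnitude` px."""
    h, w = shape
    corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], float)
    moved = corners + rng.uniform(-magnitude, magnitude, size=(4, 2))
    return estimate_homography_dlt(corners, moved)


class TestHomography:
    def test_h33_normalization(self):
        h = Homography(2 * np.eye(3))
        assert h.matrix[2, 2] == 1.0
        np.testing.assert_allclose(h.matrix, np.eye(3))

    def test_singular_matrix_rejected(self):
        m = np.ones((3, 3))
        with pytest.raises(ValueError, match="singular"):
            Homography(m)

    def test_composition_matches_sequential_application(self, rng):
        h1 = random_bounded_homography(rng)
        h2 = random_bounded_homography(rng)
        pts = rng.uniform(100, 800, size=(10, 2))
        np.testing.assert_allclose(
            (h2 @ h1).apply(pts), h2.apply(h1.apply(pts)), atol=1e-9
        )

    def test_serialization_round_trip(self, rng):
        h = random_bounded_homography(rng)
        back = Homography.from_list(h.to_list())
        np.testing.assert_allclose(back.matrix, h.matrix)


class TestDlt:
    def test_identity_recovered_from_four_points(self):
        pts = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        h = estimate_homography_dlt(pts, pts)
        assert np.abs(h.matrix - np.eye(3)).max() < 1e-10

    def test_translation_recovered_exactly(self):
        src = np.array([[0, 0], [100, 0], [100, 80], [0, 80]], float)
        h0 = np.array([[1, 0, 12.5], [0, 1, -7.0], [0, 0, 1.0]])
        dst = src + [12.5, -7.0]
        h = estimate_homography_dlt(src, dst)
        assert np.abs(h.matrix - h0).max() < 1e-8

    @pytest.mark.parametrize("n_points", [4, 20])
    def test_random_perspective_recovered(self, rng, n_points):
        for _ in range(10):
            h0 = random_bounded_homography(rng, magnitude=20.0)
            src = rng.uniform(50, 900, size=(n_points, 2))
            h = estimate_homography_dlt(src, h0.apply(src))
            assert h.corner_error(h0, (960, 1280)) < 1e-6

    def test_agrees_with_skimage_estimator(self, rng):
        """Independent oracle: scikit-image's ProjectiveTransform fit."""
        from skimage.transform import ProjectiveTransform

        src = rng.uniform(0, 500, size=(12, 2))
        h0 = random_bounded_homography(rng, shape=(500, 500), magnitude=15.0)
        dst = h0.apply(src) + rng.normal(0, 0.5, size=src.shape)
        ours = estimate_homography_dlt(src, dst)
        ref = ProjectiveTransform()
        assert ref.estimate(src, dst)
        theirs = Homography(ref.params)
        # both minimize the Hartley-normalized algebraic error; on noisy data
        # they agree up to numerical conditioning of the two SVDs
        assert ours.corner_error(theirs, (500, 500)) < 1e-4

    def test_collinear_points_rejected(self):
        src = np.array([[0, 0], [1, 1], [2, 2], [5, 0]], float)
        with pytest.raises(DegenerateConfigurationError, match="collinear"):
            estimate_homography_dlt(src, src)

    def test_too_few_points_rejected(self):
        pts = np.zeros((3, 2))
        with pytest.raises(ValueError, match=">= 4"):
            estimate_homography_dlt(pts, pts)


def _kpset(xy, desc):
    xy = np.asarray(xy, float)
    return KeypointSet(
        xy=xy,
        scales=np.ones(len(xy)),
        orientations=np.zeros(len(xy)),
        descriptors=np.asarray(desc, float),
    )


class TestMatching:
    def test_agrees_with_quadratic_loop_oracle(self, rng):
        mov = _kpset(rng.uniform(0, 10, (5, 2)), rng.uniform(0, 1, (5, 8)))
        ref = _kpset(rng.uniform(0, 10, (5, 2)), rng.uniform(0, 1, (5, 8)))
        got = match_descriptors(mov, ref)
        for i in range(5):
            dists = sorted(
                (float(np.linalg.norm(mov.descriptors[i] - ref.descriptors[j])), j)
                for j in range(5)
            )
            assert got.reference_idx[i] == dists[0][1]
            assert got.distance[i] == pytest.approx(dists[0][0])
            assert got.second_distance[i] == pytest.approx(dists[1][0])

    def test_self_match_has_zero_distance(self, rng):
        kps = _kpset(rng.uniform(0, 10, (6, 2)), rng.uniform(0, 1, (6, 16)))
        got = match_descriptors(kps, kps)
        np.testing.assert_array_equal(got.reference_idx, np.arange(6))
        assert got.distance.max() == 0.0

    def test_single_reference_keypoint_fails_ratio_test(self, rng):
        mov = _kpset(rng.uniform(0, 10, (3, 2)), rng.uniform(0, 1, (3, 4)))
        ref = _kpset([[1.0, 1.0]], rng.uniform(0, 1, (1, 4)))
        got = match_descriptors(mov, ref)
        assert np.isinf(got.second_distance).all()
        assert len(ratio_filter(got, 0.75)) == 0

    def test_descriptor_length_mismatch_raises(self, rng):
        a = _kpset([[0, 0]], np.zeros((1, 8)))
        b = _kpset([[0, 0]], np.zeros((1, 16)))
        with pytest.raises(ValueError, match="descriptor length"):
            match_descriptors(a, b)


class TestRatioFilter:
    def _matches(self, pairs):
        d = np.array([p[0] for p in pairs], float)
        s = np.array([p[1] for p in pairs], float)
        n = len(pairs)
        return MatchSet(
            moving_idx=np.arange(n),
            reference_idx=np.arange(n),
            distance=d,
            second_distance=s,
        )

    def test_below_threshold_kept(self):
        assert len(ratio_filter(self._matches([(0.5, 1.0)]), 0.75)) == 1

    def test_exact_threshold_discarded(self):
        assert len(ratio_filter(self._matches([(0.75, 1.0)]), 0.75)) == 0

    def test_ratio_one_requires_strict_improvement(self):
        m = self._matches([(1.0, 1.0), (0.99, 1.0)])
        kept = ratio_filter(m, 1.0)
        assert list(kept.distance) == [0.99]

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            ratio_filter(self._matches([(0.1, 1.0)]), 0.0)


class TestRansac:
    def _make_matches(self, rng, h0, n_inliers, n_outliers, noise=0.0):
        src = rng.uniform(50, 1200, size=(n_inliers + n_outliers, 2))
        src[:, 1] = rng.uniform(50, 900, size=len(src))
        dst = h0.apply(src)
        if noise:
            dst[:n_inliers] += rng.normal(0, noise, size=(n_inliers, 2))
        if n_outliers:
            dst[n_inliers:] = rng.uniform(0, 1280, size=(n_outliers, 2))
            dst[n_inliers:, 1] = rng.uniform(0, 960, size=n_outliers)
        n = len(src)
        mov = _kpset(src, np.zeros((n, 4)))
        ref = _kpset(dst, np.zeros((n, 4)))
        matches = MatchSet(
            moving_idx=np.arange(n),
            reference_idx=np.arange(n),
            distance=np.zeros(n),
            second_distance=np.ones(n),
        )
        return matches, mov, ref

    def test_outlier_free_matches_reduce_to_global_dlt(self, rng):
        h0 = random_bounded_homography(rng)
        matches, mov, ref = self._make_matches(rng, h0, 40, 0)
        result = estimate_homography_ransac(matches, mov, ref, seed=3)
        assert result.success
        assert result.n_inliers == 40
        direct = estimate_homography_dlt(mov.xy, ref.xy)
        np.testing.assert_allclose(result.homography.matrix, direct.matrix, atol=1e-9)

    def test_resists_thirty_percent_outliers(self, rng):
        ok = 0
        for seed in range(10):
            h0 = random_bounded_homography(rng)
            matches, mov, ref = self._make_matches(rng, h0, 70, 30)
            result = estimate_homography_ransac(matches, mov, ref, seed=seed)
            if result.success and result.homography.corner_error(h0, (960, 1280)) < 1.0:
                ok += 1
        assert ok >= 9

    def test_inlier_residuals_bounded_by_threshold(self, rng):
        h0 = random_bounded_homography(rng)
        matches, mov, ref = self._make_matches(rng, h0, 50, 20, noise=1.0)
        params = RansacParams(inlier_threshold_px=3.0)
        result = estimate_homography_ransac(matches, mov, ref, params, seed=0)
        assert (result.residuals[result.inlier_indices] <= 3.0).all()

    def test_fewer_than_four_matches_raises(self, rng):
        h0 = random_bounded_homography(rng)
        matches, mov, ref = self._make_matches(rng, h0, 3, 0)
        with pytest.raises(ValueError, match=">= 4"):
            estimate_homography_ransac(matches, mov, ref, seed=0)

    def test_collinear_geometry_yields_flagged_failure(self, rng):
        # all source points on one line: every minimal sample is degenerate
        n = 12
        src = np.column_stack([np.linspace(0, 100, n), np.linspace(0, 50, n)])
        mov = _kpset(src, np.zeros((n, 4)))
        ref = _kpset(src + 5.0, np.zeros((n, 4)))
        matches = MatchSet(
            moving_idx=np.arange(n),
            reference_idx=np.arange(n),
            distance=np.zeros(n),
            second_distance=np.ones(n),
        )
        result = estimate_homography_ransac(matches, mov, ref, seed=0)
        assert not result.success
        assert result.homography is None

    def test_deterministic_given_seed(self, rng):
        h0 = random_bounded_homography(rng)
        matches, mov, ref = self._make_matches(rng, h0, 60, 20, noise=0.5)
        r1 = estimate_homography_ransac(matches, mov, ref, seed=11)
        r2 = estimate_homography_ransac(matches, mov, ref, seed=11)
        np.testing.assert_array_equal(r1.homography.matrix, r2.homography.matrix)
        np.testing.assert_array_equal(r1.inlier_indices, r2.inlier_indices)

    def test_iteration_budget_is_proportional_and_clamped(self):
        p = RansacParams()
        assert p.budget(10) == 1000
        assert p.budget(150) == 1500
        assert p.budget(10_000) == 20_000


class TestWarping:
    def test_identity_warp_is_bitwise_equal(self, rng):
        img = rng.integers(0, 256, size=(40, 50), dtype=np.uint8)
        out = warp_image(img, Homography.identity(), mode="bilinear")
        np.testing.assert_array_equal(out, img)

    def test_integer_translation_with_nearest(self, rng):
        img = rng.integers(0, 256, size=(30, 30), dtype=np.uint8)
        h = Homography(np.array([[1, 0, 5], [0, 1, 3], [0, 0, 1]], float))
        out = warp_image(img, h, mode="nearest")
        np.testing.assert_array_equal(out[3:, 5:], img[:-3, :-5])
        assert (out[:3, :] == 0).all() and (out[:, :5] == 0).all()

    def test_round_trip_intensity_error_small(self, rng):
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(rng.uniform(0, 255, (120, 160)), 2).astype(np.uint8)
        h = random_bounded_homography(rng, shape=(120, 160), magnitude=8.0)
        there = warp_image(img, h)
        back = warp_image(there, h.inverse())
        interior = (slice(20, -20), slice(20, -20))
        mae = np.abs(back[interior].astype(float) - img[interior].astype(float)).mean()
        assert mae < 2.0

    def test_mask_warp_stays_binary(self, rng):
        mask = (rng.uniform(size=(50, 60)) < 0.3).astype(np.uint8)
        h = random_bounded_homography(rng, shape=(50, 60), magnitude=4.0)
        out = warp_mask(mask, h)
        assert set(np.unique(out)) <= {0, 1}


class TestWarpPolygon:
    def test_identity_and_translation(self):
        tri = PolygonRegion(xs=[0.0, 5.0, 2.0], ys=[0.0, 1.0, 6.0])
        same = warp_polygon(tri, Homography.identity())
        np.testing.assert_allclose(same.vertices, tri.vertices)
        shift = Homography(np.array([[1, 0, 3], [0, 1, -2], [0, 0, 1]], float))
        moved = warp_polygon(tri, shift)
        np.testing.assert_allclose(moved.vertices, tri.vertices + [3, -2])

    def test_composition_group_property(self, rng):
        tri = PolygonRegion(xs=[100.0, 400.0, 250.0], ys=[100.0, 150.0, 500.0])
        h1 = random_bounded_homography(rng)
        h2 = random_bounded_homography(rng)
        a = warp_polygon(warp_polygon(tri, h1), h2)
        b = warp_polygon(tri, h2 @ h1)
        np.testing.assert_allclose(a.vertices, b.vertices, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_polygon_warp_consistent_with_image_warp(self, seed):
        """Warping a polygon then rasterizing nearly equals rasterizing then
        warping the mask (cross-path consistency)."""
        rng = np.random.default_rng(seed)
        angles = np.linspace(0, 2 * np.pi, 14, endpoint=False)
        radii = 16 * (1 + rng.uniform(-0.2, 0.2, 14))
        cx, cy = rng.uniform(35, 65, 2)
        poly = PolygonRegion(
            xs=cx + radii * np.cos(angles), ys=cy + radii * np.sin(angles)
        )
        h = random_bounded_homography(rng, shape=(100, 100), magnitude=6.0)
        a = rasterize([warp_polygon(poly, h)], (100, 100))
        b = warp_mask(rasterize([poly], (100, 100)), h)
        inter = np.logical_and(a, b).sum()
        union = np.logical_or(a, b).sum()
        assert inter / union >= 0.95


class TestMorphology:
    def test_radius_zero_is_identity(self, rng):
        m = (rng.uniform(size=(10, 10)) < 0.5).astype(np.uint8)
        np.testing.assert_array_equal(dilate(m, 0), m)
        np.testing.assert_array_equal(erode(m, 0), m)

    def test_single_pixel_disk_dilation_is_plus_shape(self):
        m = np.zeros((5, 5), np.uint8)
        m[2, 2] = 1
        out = dilate(m, 1, "disk")
        expected = np.zeros((5, 5), np.uint8)
        for dr, dc in [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)]:
            expected[2 + dr, 2 + dc] = 1
        np.testing.assert_array_equal(out, expected)

    def test_square_erosion_of_solid_square_leaves_center(self):
        m = np.zeros((7, 7), np.uint8)
        m[2:5, 2:5] = 1
        out = erode(m, 1, "disk")
        expected = np.zeros((7, 7), np.uint8)
        expected[3, 3] = 1
        np.testing.assert_array_equal(out, expected)

    def test_dilation_is_extensive_and_erosion_antiextensive(self, rng):
        for r in (1, 2):
            m = (rng.uniform(size=(20, 20)) < 0.3).astype(np.uint8)
            assert (dilate(m, r) >= m).all()
            assert (erode(m, r) <= m).all()
            # closing (dilate then erode) is extensive
            assert (erode(dilate(m, r), r) >= m).all()

    def test_erosion_is_dual_of_dilation_under_complement(self, rng):
        m = np.zeros((24, 24), np.uint8)
        m[8:16, 6:18] = (rng.uniform(size=(8, 12)) < 0.6).astype(np.uint8)
        for r in (1, 2):
            a = erode(m, r)
            b = 1 - dilate(1 - m, r)
            np.testing.assert_array_equal(a, b)


class TestDetectKeypoints:
    def test_constant_image_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            kps = detect_keypoints(np.full((64, 64), 7, dtype=np.uint8))
        assert len(kps) == 0

    def test_detection_is_deterministic(self, small_scene):
        _, scene, _ = small_scene
        img = scene.images[Band.REDEDGE]
        a = detect_keypoints(img)
        b = detect_keypoints(img.copy())
        np.testing.assert_array_equal(a.xy, b.xy)
        np.testing.assert_array_equal(a.descriptors, b.descriptors)

    def test_repeatability_under_translation(self, small_scene):
        """Most keypoints reappear within 1 px after a 15-px shift."""
        _, scene, _ = small_scene
        img = scene.images[Band.REDEDGE].astype(float)
        shifted = np.zeros_like(img)
        shifted[:, 15:] = img[:, :-15]
        a = detect_keypoints(img)
        b = detect_keypoints(shifted)
        interior = a.xy[(a.xy[:, 0] > 20) & (a.xy[:, 0] < img.shape[1] - 40)]
        expected = interior + [15.0, 0.0]
        from scipy.spatial import cKDTree

        d, _ = cKDTree(b.xy).query(expected)
        assert (d <= 1.0).mean() >= 0.8
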