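"""Extraction chain stages against brute-force oracles, plus the full chain."""

import numpy as np
import pytest
from scipy import ndimage

from tfccmorph import (AnatomicalFrame, LabelVolume, PipelineConfig,
                       boundary_voxels, candidate_overlap, extract_footprint,
                       largest_component, measure_patch, patch_area,
                       ransac_plane, smooth_labels)
from tfccmorph.errors import ExtractionError, GeometryError, SchemaError


class TestSmoothLabels:
    def test_sigma_zero_is_identity(self, rng):
        vox = rng.integers(0, 4, (8, 8, 8)).astype(np.int16)
        vol = LabelVolume(vox)
        assert np.array_equal(smooth_labels(vol, 0.0).voxels, vox)

    def test_uniform_volume_unchanged(self):
        vol = LabelVolume(np.full((6, 6, 6), 2, np.int16))
        assert np.array_equal(smooth_labels(vol, 2.0).voxels, vol.voxels)

    def test_speckle_removal_matches_convolution_oracle(self):
        vox = np.full((9, 9, 9), 2, np.int16)
        vox[4, 4, 4] = 3  # isolated speckle
        vol = LabelVolume(vox)
        out = smooth_labels(vol, 1.0)
        assert out.voxels[4, 4, 4] == 2
        # independent oracle: blur each one-hot indicator, argmax, low-label ties
        scores = {lab: ndimage.gaussian_filter((vox == lab).astype(float), 1.0)
                  for lab in np.unique(vox)}
        labs = sorted(scores)
        stack = np.stack([scores[l] for l in labs])
        expected = np.asarray(labs)[np.argmax(stack, axis=0)]
        assert np.array_equal(out.voxels, expected)

    def test_no_new_labels(self, rng):
        vox = rng.integers(0, 3, (10, 10, 10)).astype(np.int16)
        out = smooth_labels(LabelVolume(vox), 1.5)
        assert set(np.unique(out.voxels)) <= set(np.unique(vox))


class TestBoundaryVoxels:
    def test_empty_and_single_voxel(self):
        empty = np.zeros((5, 5, 5), bool)
        assert not boundary_voxels(empty, (1, 1, 1)).any()
        single = empty.copy(); single[2, 2, 2] = True
        out = boundary_voxels(single, (1, 1, 1))
        assert out.sum() == 1 and out[2, 2, 2]

    def test_solid_cube_surface_count(self):
        """5^3 cube: exactly the 98 non-interior voxels (5^3 - 3^3)."""
        mask = np.zeros((9, 9, 9), bool)
        mask[2:7, 2:7, 2:7] = True
        out = boundary_voxels(mask, (1, 1, 1), 0.1)
        assert out.sum() == 98
        # 6-neighborhood erosion oracle
        oracle = mask & ~ndimage.binary_erosion(mask)
        assert np.array_equal(out, oracle)

    def test_result_is_subset_of_mask(self, rng):
        mask = ndimage.binary_dilation(rng.random((12, 12, 12)) < 0.05)
        out = boundary_voxels(mask, (0.5, 0.5, 1.0))
        assert not (out & ~mask).any()


class TestCandidateOverlap:
    def _slabs(self):
        a = np.zeros((10, 10, 10), bool); a[:, :, 0:5] = True
        b = np.zeros((10, 10, 10), bool); b[:, :, 5:10] = True
        return a, b

    def test_face_adjacent_slabs_give_the_touching_layers(self):
        """Brute-force oracle: voxels within one voxel of both boundaries."""
        a, b = self._slabs()
        h = (1.0, 1.0, 1.0)
        ab = boundary_voxels(a, h)
        bb = boundary_voxels(b, h)
        out = candidate_overlap(ab, bb, 1.0, h)
        # exhaustive pairwise-distance oracle on the touching interface
        pa = np.argwhere(ab); pb = np.argwhere(bb)
        expected = np.zeros_like(a)
        for idx in np.ndindex(a.shape):
            da = np.abs(pa - idx).max(axis=1).min()  # Chebyshev to boundary A
            db = np.abs(pb - idx).max(axis=1).min()
            expected[idx] = da <= 1 and db <= 1
        # the touching layers are exactly z in {4, 5}
        assert np.array_equal(np.unique(np.argwhere(out)[:, 2]), [4, 5])
        assert not (out & ~expected).any()
        assert out.sum() == 200

    def test_argument_swap_symmetry(self):
        a, b = self._slabs()
        h = (1.0, 1.0, 1.0)
        ab, bb = boundary_voxels(a, h), boundary_voxels(b, h)
        assert np.array_equal(candidate_overlap(ab, bb, 1.0, h),
                              candidate_overlap(bb, ab, 1.0, h))

    def test_distant_structures_give_empty_overlap(self):
        a = np.zeros((12, 12, 12), bool); a[:, :, 0:2] = True
        b = np.zeros((12, 12, 12), bool); b[:, :, 9:12] = True
        h = (1.0, 1.0, 1.0)
        out = candidate_overlap(boundary_voxels(a, h), boundary_voxels(b, h),
                                2.0, h)
        assert not out.any()

    def test_radius_below_spacing_is_an_error(self):
        a, b = self._slabs()
        with pytest.raises(ValueError):
            candidate_overlap(a, b, 0.5, (1.0, 1.0, 1.0))


class TestLargestComponent:
    def test_single_component_unchanged(self):
        m = np.zeros((6, 6, 6), bool); m[1:4, 1:4, 1:4] = True
        assert np.array_equal(largest_component(m, 26, 1), m)

    def test_size_filter_and_selection(self):
        m = np.zeros((20, 8, 8), bool)
        m[0:1, 0:5, 0:8] = True       # 40 voxels
        m[5:6, 0:1, 0:7] = True       # 7 voxels
        m[10:11, 0:1, 0:3] = True     # 3 voxels
        out = largest_component(m, 6, min_size=5)
        assert out.sum() == 40 and out[0, 0, 0]

    def test_tie_breaks_to_lexicographically_smallest_seed(self):
        m = np.zeros((8, 8, 8), bool)
        m[6, 6, 6] = True
        m[1, 1, 1] = True
        out = largest_component(m, 26, 1)
        assert out.sum() == 1 and out[1, 1, 1]

    def test_nothing_reaches_min_size_returns_empty(self):
        m = np.zeros((5, 5, 5), bool); m[0, 0, 0] = True
        out = largest_component(m, 26, min_size=10)
        assert not out.any()


class TestRansacPlane:
    def test_planted_plane_recovers_true_inlier_set(self, rng):
        xy = rng.uniform(-5, 5, size=(100, 2))
        inliers = np.column_stack([xy, np.zeros(100)])
        outliers = np.column_stack([rng.uniform(-5, 5, (10, 2)),
                                    np.full(10, 5.0)])
        pts = np.concatenate([inliers, outliers])
        plane, flags = ransac_plane(pts, 0.1, 500, seed=42)
        assert abs(abs(plane.normal[2]) - 1.0) < 1e-6
        assert flags[:100].all() and not flags[100:].any()
        # least-squares oracle on the true inlier set: plane passes through z=0
        assert abs(plane.signed_distance(inliers).max()) < 1e-9

    def test_coplanar_points_all_inliers_zero_residual(self, rng):
        pts = np.column_stack([rng.uniform(0, 3, (30, 2)), np.full(30, 1.5)])
        plane, flags = ransac_plane(pts, 0.05, 100, seed=0)
        assert flags.all()
        assert np.abs(plane.signed_distance(pts)).max() < 1e-9

    def test_three_points(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        plane, flags = ransac_plane(pts, 0.01, 10, seed=1)
        assert flags.all()
        assert np.abs(plane.signed_distance(pts)).max() < 1e-12

    def test_degenerate_inputs(self):
        with pytest.raises(GeometryError):
            ransac_plane(np.zeros((2, 3)), 0.1, 10, 0)
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(GeometryError):
            ransac_plane(line, 0.1, 10, 0)

    def test_deterministic_for_fixed_seed(self, rng):
        pts = rng.normal(size=(50, 3))
        p1, f1 = ransac_plane(pts, 0.3, 200, seed=5)
        p2, f2 = ransac_plane(pts, 0.3, 200, seed=5)
        assert p1 == p2 and np.array_equal(f1, f2)


class TestExtractFootprint:
    def test_recovers_phantom_area_within_five_percent(self, fast_phantom,
                                                       fast_patch):
        _, _, truth = fast_phantom
        area = patch_area(fast_patch)
        assert area == pytest.approx(truth.deep_area, rel=0.05)

    def test_deterministic(self, fast_phantom, fast_patch):
        _, volume, truth = fast_phantom
        cfg = PipelineConfig(seed=3, ransac_iterations=300)
        again = extract_footprint(volume, 3, 2, cfg,
                                  truth.landmark_positions["fovea"])
        assert np.array_equal(again.voxel_indices, fast_patch.voxel_indices)
        assert again.plane == fast_patch.plane

    def test_missing_soft_label_is_a_precondition_error(self, fast_phantom):
        _, volume, truth = fast_phantom
        stripped = volume.copy()
        stripped.voxels[stripped.voxels == 3] = 0
        with pytest.raises(SchemaError):
            extract_footprint(stripped, 3, 2, PipelineConfig(seed=0),
                              truth.landmark_positions["fovea"])

    def test_no_contact_reports_the_emptying_stage(self):
        vox = np.zeros((20, 20, 20), np.int16)
        vox[2:18, 2:18, 2:5] = 2
        vox[2:18, 2:18, 12:15] = 3  # 7 voxels away from the bone
        vol = LabelVolume(vox, (0.2, 0.2, 0.2))
        with pytest.raises(ExtractionError) as err:
            extract_footprint(vol, 3, 2, PipelineConfig(seed=0),
                              (2.0, 2.0, 2.0))
        assert err.value.stage == "overlap"

    def test_patch_lies_on_the_soft_boundary(self, fast_phantom, fast_patch):
        _, volume, _ = fast_phantom
        sm = smooth_labels(volume, 1.0)
        soft_b = boundary_voxels(sm.voxels == 3, volume.spacing, 0.1)
        assert soft_b[tuple(fast_patch.voxel_indices.T)].all()

    def test_rotation_equivariance(self, fast_phantom):
        """90-degree in-plane rotation of the grid leaves the area invariant."""
        _, volume, truth = fast_phantom
        cfg = PipelineConfig(seed=3, ransac_iterations=300)
        base = extract_footprint(volume, 3, 2, cfg,
                                 truth.landmark_positions["fovea"])
        a0 = patch_area(base)

        rot = LabelVolume(np.ascontiguousarray(np.rot90(volume.voxels,
                                                        axes=(0, 1))),
                          volume.spacing, (0.0, 0.0, 0.0),
                          volume.axis_orientation, dict(volume.label_schema))
        # rotate the fovea seed with the same index map: (i,j,k)->(N1-1-j,i,k)
        f = np.asarray(truth.landmark_positions["fovea"])
        idx = (f - np.asarray(volume.origin)) / np.asarray(volume.spacing)
        n1 = volume.shape[1]
        new_idx = np.array([n1 - 1 - idx[1], idx[0], idx[2]])
        seed_world = new_idx * np.asarray(volume.spacing)
        patch = extract_footprint(rot, 3, 2, cfg, seed_world)
        assert patch_area(patch) == pytest.approx(a0, rel=0.01)
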