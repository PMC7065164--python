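"""Long-axis alignment: PCA axes, registration, distance maps, majority
masks."""

import numpy as np
import pytest

from hippoprof import (
    EmptyInputError,
    ImageVolume,
    PhantomSpec,
    RigidPose,
    Segmentation,
    Transform,
    build_distance_map,
    build_group_template,
    majority_mask,
    make_subject,
    principal_axis,
    propagate_distance_map,
    register_subject,
    reorient_to_ap,
    resample,
    slice_distance_table,
)
from hippoprof.alignment import AlignmentError, DistanceMap


def _box_segmentation(extent=(8, 40, 8), shape=(60, 60, 60),
                      rotation=None) -> Segmentation:
    affine = np.eye(4)
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2
    idx = np.indices(shape, dtype=float)
    world = idx + affine[:3, 3][:, None, None, None]
    if rotation is not None:
        world = np.einsum("ab,b...->a...", np.linalg.inv(rotation), world)
    half = np.asarray(extent) / 2
    inside = np.all([np.abs(world[i]) <= half[i] for i in range(3)], axis=0)
    return Segmentation(inside.astype(float), affine)


def _rot_z(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0],
                     [np.sin(a), np.cos(a), 0], [0, 0, 1]])


class TestPrincipalAxis:
    def test_axis_aligned_box_gives_plus_y(self):
        axis, evals = principal_axis(_box_segmentation())
        assert np.allclose(axis, [0, 1, 0], atol=1e-6)
        assert evals[0] > evals[1]

    def test_rotated_box_axis_recovered_within_half_degree(self):
        rot = _rot_z(30.0)
        axis, _ = principal_axis(_box_segmentation(rotation=rot))
        expected = rot @ np.array([0.0, 1.0, 0.0])
        angle = np.rad2deg(np.arccos(np.clip(abs(axis @ expected), -1, 1)))
        assert angle < 0.5

    def test_sphere_is_degenerate(self):
        shape = (40, 40, 40)
        affine = np.eye(4)
        affine[:3, 3] = -19.5
        idx = np.indices(shape, dtype=float) - 19.5
        seg = Segmentation((np.sum(idx**2, axis=0) <= 15**2).astype(float),
                           affine)
        with pytest.raises(AlignmentError):
            principal_axis(seg)

    def test_tiny_mask_rejected(self):
        seg = Segmentation(np.zeros((10, 10, 10)), np.eye(4))
        seg.data[5, 5, 5] = 1.0
        with pytest.raises(EmptyInputError):
            principal_axis(seg)


class TestReorient:
    def test_aligned_straight_phantom_maps_to_identity(self, t1_grid):
        spec = PhantomSpec(arc_sagitta_mm=0.0, seed=2)
        sub = make_subject(spec, with_images=False)
        t = reorient_to_ap(sub.t1_like, sub.mask_left, sub.mask_right)
        assert np.allclose(t.matrix[:3, :3], np.eye(3), atol=1e-6)

    @pytest.mark.parametrize("angles", [(15.0, 0.0, -10.0), (-8.0, 0.0, 12.0)])
    def test_known_pose_rotation_recovered_within_one_degree(self, angles):
        spec = PhantomSpec(arc_sagitta_mm=0.0, seed=2,
                           pose=RigidPose(angles))
        sub = make_subject(spec, with_images=False)
        t = reorient_to_ap(sub.t1_like, sub.mask_left, sub.mask_right)
        # composing recovery with the pose must leave +y fixed
        combined = t.matrix[:3, :3] @ spec.pose.transform().matrix[:3, :3]
        residual = np.rad2deg(np.arccos(np.clip(combined[1, 1], -1, 1)))
        assert residual < 1.0

    def test_post_transform_axes_lie_along_ap(self):
        spec = PhantomSpec(seed=4, pose=RigidPose((10.0, 6.0, -14.0)))
        sub = make_subject(spec, with_images=False)
        t = reorient_to_ap(sub.t1_like, sub.mask_left, sub.mask_right)
        for seg in (sub.mask_left, sub.mask_right):
            axis, _ = principal_axis(seg)
            rotated = t.matrix[:3, :3] @ axis
            angle = np.rad2deg(np.arccos(np.clip(abs(rotated[1]), -1, 1)))
            assert angle < 2.0

    def test_disagreeing_axes_rejected(self):
        left = _box_segmentation()
        right = _box_segmentation(rotation=_rot_z(60.0))
        vol = ImageVolume(np.zeros(left.data.shape), left.affine)
        with pytest.raises(AlignmentError):
            reorient_to_ap(vol, left, right)


class TestRegistration:
    def test_self_registration_is_identity(self, base_subject):
        res = register_subject(base_subject.t1_like, base_subject.t1_like,
                               iterations=60)
        assert np.allclose(res.transform.matrix, np.eye(4), atol=1e-3)
        assert res.similarity <= -0.99

    def test_isotropic_scale_recovered_within_two_percent(self, base_subject):
        t1 = base_subject.t1_like
        scale = Transform(np.diag([1.1, 1.1, 1.1, 1.0]))
        scaled = resample(t1, scale, t1)  # content enlarged 1.1x
        res = register_subject(scaled, t1, iterations=150)
        recovered = np.linalg.norm(res.transform.matrix[:3, :3], axis=0)
        assert np.allclose(recovered, 1.0 / 1.1, rtol=0.02)

    def test_cost_masking_ignores_hippocampal_atrophy(self, base_subject):
        """Ablating the hippocampi (severe simulated atrophy) must not move
        the registration when the cost is masked there."""
        t1 = base_subject.t1_like
        shift = Transform.from_rotation_translation(np.eye(3),
                                                    (2.0, -3.0, 1.0))
        moved = resample(t1, shift, t1)
        ablated = moved.like(moved.data.copy())
        both = (base_subject.mask_left.binary
                | base_subject.mask_right.binary)
        excl = Segmentation(
            np.clip(base_subject.mask_left.data
                    + base_subject.mask_right.data, 0, 1), t1.affine.copy())
        ablated_region = resample(
            ImageVolume(both.astype(float), t1.affine), shift, t1
        ).data > 0.5
        ablated.data[ablated_region] = 1000.0  # hippocampi erased to background
        res_intact = register_subject(moved, t1, exclusion_mask=excl,
                                      iterations=100)
        res_ablated = register_subject(ablated, t1, exclusion_mask=excl,
                                       iterations=100)
        dev = np.abs(res_intact.transform.matrix[:3, 3]
                     - res_ablated.transform.matrix[:3, 3])
        assert np.all(dev < 0.5)


class TestGroupTemplate:
    def test_identical_inputs_fixed_point(self, base_subject):
        t1 = base_subject.t1_like
        template, transforms = build_group_template([t1, t1], n_affine=1,
                                                    iterations=60)
        assert np.allclose(template.data, t1.data, atol=1e-6)
        for t in transforms:
            assert np.allclose(t.matrix, np.eye(4), atol=5e-3)

    def test_translated_copies_average_midway(self, base_subject):
        t1 = base_subject.t1_like
        plus = resample(t1, Transform.from_rotation_translation(
            np.eye(3), (0.0, 2.0, 0.0)), t1)
        minus = resample(t1, Transform.from_rotation_translation(
            np.eye(3), (0.0, -2.0, 0.0)), t1)
        template, transforms = build_group_template([plus, minus],
                                                    n_affine=2,
                                                    iterations=100)
        shifts = [t.matrix[1, 3] for t in transforms]
        # transforms must pull each copy back toward the centre: -2 and +2
        assert abs(shifts[0] + 2.0) < 0.5
        assert abs(shifts[1] - 2.0) < 0.5

    def test_needs_at_least_two_subjects(self, base_subject):
        with pytest.raises(EmptyInputError):
            build_group_template([base_subject.t1_like])


class TestDistanceMap:
    @pytest.mark.parametrize("n_slices,spacing,first,last", [
        (218, 1.0, 1.0, 218.0),   # full-length template: distances 1-218 mm
        (50, 1.0, 1.0, 50.0),
        (30, 2.0, 2.0, 60.0),
    ])
    def test_slice_ladder(self, n_slices, spacing, first, last):
        affine = np.diag([1.0, spacing, 1.0, 1.0])
        vol = ImageVolume(np.zeros((4, n_slices, 4)), affine)
        dmap = build_distance_map(vol)
        ladder = dmap.data[0, :, 0]
        assert ladder[0] == first
        assert ladder[-1] == last
        assert np.allclose(np.diff(ladder), spacing)
        assert np.all(np.diff(ladder) > 0)

    def test_identity_propagation_reproduces_ladder(self):
        vol = ImageVolume(np.zeros((8, 60, 8)), np.eye(4))
        dmap = build_distance_map(vol)
        seg = Segmentation(np.zeros((8, 60, 8)), np.eye(4))
        seg.data[2:6, 9:49, 2:6] = 1.0  # 1-based slices 10..49
        prop = propagate_distance_map(dmap, Transform.identity(), vol)
        table = slice_distance_table(prop, seg)
        assert np.allclose(table.mean_distance_mm,
                           np.arange(10.0, 50.0))
        assert table.is_monotone

    def test_ap_translation_shifts_distances(self):
        vol = ImageVolume(np.zeros((8, 60, 8)), np.eye(4))
        dmap = build_distance_map(vol)
        seg = Segmentation(np.zeros((8, 60, 8)), np.eye(4))
        seg.data[2:6, 20:40, 2:6] = 1.0
        t = 7.0  # template -> subject shift along AP
        tr = Transform.from_rotation_translation(np.eye(3), (0.0, t, 0.0))
        prop = propagate_distance_map(dmap, tr, vol)
        table = slice_distance_table(prop, seg)
        base = slice_distance_table(
            propagate_distance_map(dmap, Transform.identity(), vol), seg)
        assert np.allclose(table.mean_distance_mm,
                           base.mean_distance_mm - t, atol=1e-9)

    def test_affine_ap_scaling_matches_analytic_map(self):
        vol = ImageVolume(np.zeros((8, 60, 8)), np.eye(4))
        dmap = build_distance_map(vol)
        seg = Segmentation(np.zeros((8, 60, 8)), np.eye(4))
        seg.data[2:6, 10:50, 2:6] = 1.0
        s = 1.2
        tr = Transform(np.diag([1.0, s, 1.0, 1.0]))
        prop = propagate_distance_map(dmap, tr, vol)
        table = slice_distance_table(prop, seg)
        # subject world y = s * template y; with this identity-origin grid
        # the ladder reads (y_template + 1) mm, so slice j maps to j/s + 1
        expected = table.slice_indices.astype(float) / s + 1.0
        assert np.allclose(table.mean_distance_mm, expected, atol=0.5)
        assert table.is_monotone

    def test_out_of_field_distances_warn(self):
        vol = ImageVolume(np.zeros((8, 30, 8)), np.eye(4))
        dmap = build_distance_map(vol)
        seg = Segmentation(np.zeros((8, 30, 8)), np.eye(4))
        seg.data[2:6, 5:25, 2:6] = 1.0
        tr = Transform.from_rotation_translation(np.eye(3), (0.0, -20.0, 0.0))
        prop = propagate_distance_map(dmap, tr, vol)
        with pytest.warns(UserWarning):
            slice_distance_table(prop, seg)


class TestMajorityMask:
    def _stack(self, arrays):
        return [Segmentation(a.astype(float), np.eye(4)) for a in arrays]

    def test_unanimity_and_absence(self):
        ones = np.ones((4, 4, 4))
        zeros = np.zeros((4, 4, 4))
        out = majority_mask(self._stack([ones, ones, zeros * 0 + 1]))
        assert out.binary.all()
        out = majority_mask(self._stack([zeros, zeros, zeros]))
        assert not out.binary.any()

    def test_exactly_half_is_included(self):
        a = np.zeros((2, 2, 2))
        b = np.zeros((2, 2, 2))
        a[0, 0, 0] = 1.0  # in exactly 2 of 4
        b[0, 0, 0] = 1.0
        out = majority_mask(self._stack([a, b, np.zeros_like(a),
                                         np.zeros_like(a)]))
        assert out.binary[0, 0, 0]

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(7)
        stacks = rng.random((7, 5, 5, 5)) > 0.5
        segs = self._stack([s for s in stacks])
        out = majority_mask(segs, threshold=0.5)
        brute = stacks.sum(axis=0) >= np.ceil(7 * 0.5)
        # inclusive at exactly half: threshold count for N=7 is ceil(3.5)=4
        assert np.array_equal(out.binary, brute)

    def test_empty_list_rejected(self):
        with pytest.raises(EmptyInputError):
            majority_mask([])


class TestMonotonicity:
    def test_positive_ap_scaling_keeps_distances_increasing(self):
        vol = ImageVolume(np.zeros((6, 40, 6)), np.eye(4))
        dmap = build_distance_map(vol)
        seg = Segmentation(np.zeros((6, 40, 6)), np.eye(4))
        seg.data[1:5, 5:35, 1:5] = 1.0
        for s in (0.7, 1.0, 1.5):
            tr = Transform(np.diag([1.0, s, 1.0, 1.0]))
            prop = propagate_distance_map(dmap, tr, vol)
            table = slice_distance_table(prop, seg)
            assert table.is_monotone
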