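"""Single-plane solvers, composite alignment, exact mode, resampling."""

import numpy as np
import pytest

from headalign import (
    DegenerateGeometryError,
    LandmarkSet,
    MisalignmentSpec,
    align_volume,
    apply_misalignment,
    apply_transform,
    cochlear_deviation,
    compute_alignment_exact,
    compute_alignment_sequential,
    compute_pitch,
    compute_roll,
    compute_yaw,
    decompose_rotation,
    transform_points,
)
from headalign.align import RigidTransform, rotation_x, rotation_y, rotation_z
from tests.conftest import random_landmarks


def _lm(rc, lc, nb):
    return LandmarkSet(right_cochlea=rc, left_cochlea=lc, nasal_bridge=nb)


ALIGNED = _lm([-30.0, 0, 0], [30.0, 0, 0], [0.0, -80.0, 0])


class TestComputeYaw:
    def test_already_aligned_gives_zero(self):
        assert compute_yaw(ALIGNED).yaw_deg == pytest.approx(0.0, abs=1e-12)

    def test_known_tangent_and_postcondition(self):
        lm = _lm([-30.0, -10.0, 0], [30.0, 10.0, 0], [0.0, -80.0, 0])
        angles = compute_yaw(lm)
        assert abs(angles.yaw_deg) == pytest.approx(np.degrees(np.arctan(20.0 / 60.0)))
        rotated = transform_points(lm.as_array(), angles.to_transform())
        assert abs(rotated[1, 1] - rotated[0, 1]) <= 1e-9  # equal cochlear y
        assert rotated[1, 0] > rotated[0, 0]  # left stays left

    def test_z_only_offset_needs_no_yaw(self):
        lm = _lm([-30.0, 0, -5.0], [30.0, 0, 5.0], [0.0, -80.0, 0])
        assert compute_yaw(lm).yaw_deg == pytest.approx(0.0, abs=1e-12)


class TestComputePitch:
    def test_equal_z_gives_zero(self):
        assert compute_pitch(ALIGNED).pitch_deg == pytest.approx(0.0, abs=1e-12)

    def test_known_tangent_and_postcondition(self):
        lm = _lm([-30.0, 0, 0], [30.0, 0, 0], [0.0, -80.0, 25.0])
        angles = compute_pitch(lm)
        assert abs(angles.pitch_deg) == pytest.approx(np.degrees(np.arctan(25.0 / 80.0)))
        rotated = transform_points(lm.as_array(), angles.to_transform())
        assert abs(rotated[2, 2] - rotated[0, 2]) <= 1e-9  # nb and rc equal z
        assert rotated[2, 1] < rotated[0, 1]  # nb stays anterior

    def test_x_offset_unaffected(self):
        lm = _lm([-30.0, 0, 0], [30.0, 0, 0], [-10.0, -80.0, 0])
        assert compute_pitch(lm).pitch_deg == pytest.approx(0.0, abs=1e-12)


class TestComputeRoll:
    def test_equal_z_gives_zero(self):
        assert compute_roll(ALIGNED).roll_deg == pytest.approx(0.0, abs=1e-12)

    def test_known_tangent_and_postcondition(self):
        lm = _lm([-30.0, 0, -5.0], [30.0, 0, 5.0], [0.0, -80.0, 0])
        angles = compute_roll(lm)
        assert abs(angles.roll_deg) == pytest.approx(np.degrees(np.arctan(10.0 / 60.0)))
        rotated = transform_points(lm.as_array(), angles.to_transform())
        assert abs(rotated[1, 2] - rotated[0, 2]) <= 1e-9
        assert rotated[1, 0] > rotated[0, 0]

    def test_y_only_offset_needs_no_roll(self):
        lm = _lm([-30.0, -5.0, 0], [30.0, 5.0, 0], [0.0, -80.0, 0])
        assert compute_roll(lm).roll_deg == pytest.approx(0.0, abs=1e-12)


class TestSequentialAlignment:
    def test_aligned_input_gives_identity(self):
        angles, transform = compute_alignment_sequential(ALIGNED)
        assert angles.yaw_deg == angles.pitch_deg == angles.roll_deg == pytest.approx(0.0)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-12)

    def test_composite_equals_ordered_product(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            lm = random_landmarks(rng)
            angles, transform = compute_alignment_sequential(lm)
            product = (
                rotation_y(angles.roll_deg)
                @ rotation_x(angles.pitch_deg)
                @ rotation_z(angles.yaw_deg)
            )
            np.testing.assert_allclose(transform.rotation, product, atol=1e-12)

    def test_roll_is_last_so_z_deviation_vanishes(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            lm = random_landmarks(rng)
            _, transform = compute_alignment_sequential(lm)
            out = transform.apply(lm.as_array())
            assert abs(out[1, 2] - out[0, 2]) <= 1e-9

    def test_residual_y_deviation_obeys_closed_form(self):
        # final cochlear y deviation = |dz after yaw| * |sin(pitch)|:
        # pitch re-tilts the yaw-aligned cochlear axis out of the y plane
        rng = np.random.default_rng(13)
        for _ in range(200):
            lm = random_landmarks(rng)
            angles, transform = compute_alignment_sequential(lm)
            out = transform.apply(lm.as_array())
            after_yaw = transform_points(
                lm.as_array(),
                RigidTransform(rotation_z(angles.yaw_deg), angles.center),
            )
            dz = after_yaw[1, 2] - after_yaw[0, 2]
            expected = abs(dz * np.sin(np.radians(angles.pitch_deg)))
            assert abs(abs(out[1, 1] - out[0, 1]) - expected) <= 1e-9


class TestExactAlignment:
    def test_aligned_input_gives_identity(self):
        transform = compute_alignment_exact(ALIGNED)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-12)

    def test_recovers_inverse_of_known_rotation(self):
        # a misalignment Q applied to an already-aligned set must be
        # undone exactly: exact(Q L) = Q^T
        lm = ALIGNED
        q = rotation_y(17.0) @ rotation_x(-28.0) @ rotation_z(41.0)
        center = lm.cochlear_midpoint
        moved = LandmarkSet.from_array(
            transform_points(lm.as_array(), RigidTransform(q, center))
        )
        transform = compute_alignment_exact(moved)
        np.testing.assert_allclose(transform.rotation, q.T, atol=1e-9)

    def test_all_three_constraints_hold_on_random_geometry(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            lm = random_landmarks(rng)
            out = compute_alignment_exact(lm).apply(lm.as_array())
            assert abs(out[1, 1] - out[0, 1]) <= 1e-9  # cochlear y
            assert abs(out[1, 2] - out[0, 2]) <= 1e-9  # cochlear z
            assert abs(out[2, 2] - out[0, 2]) <= 1e-9  # nasal bridge z

    def test_modes_agree_within_residual_angle(self):
        # the sequential solve differs from exact by two small residuals:
        # the cochlear y deviation (angle ~ resid_y / span about z) and the
        # nasal-bridge z deviation that the final roll reintroduces
        # (angle ~ resid_z_nb / lever about x); the geodesic angle between
        # the two rotations is bounded by the sum of those two angles
        rng = np.random.default_rng(15)
        for _ in range(100):
            lm = random_landmarks(rng)
            _, t_seq = compute_alignment_sequential(lm)
            t_exact = compute_alignment_exact(lm)
            rel = t_seq.rotation @ t_exact.rotation.T
            geo = np.degrees(np.arccos(np.clip((np.trace(rel) - 1) / 2, -1, 1)))
            out = t_seq.apply(lm.as_array())
            span = np.linalg.norm(lm.left_cochlea - lm.right_cochlea)
            axis = lm.left_cochlea - lm.right_cochlea
            u = lm.nasal_bridge - lm.right_cochlea
            lever = np.linalg.norm(u - np.dot(u, axis) / np.dot(axis, axis) * axis)
            alpha = np.degrees(np.arcsin(min(1.0, abs(out[1, 1] - out[0, 1]) / span)))
            gamma = np.degrees(np.arcsin(min(1.0, abs(out[2, 2] - out[0, 2]) / lever)))
            assert geo <= alpha + gamma + 1e-6

    def test_collinear_geometry_rejected(self):
        # exactly collinear points cannot pass LandmarkSet validation, so
        # exercise the solver's own guard with a minimal stand-in object
        class Collinear:
            right_cochlea = np.array([-30.0, 0.0, 0.0])
            left_cochlea = np.array([30.0, 0.0, 0.0])
            nasal_bridge = np.array([0.0, 0.0, 0.0])
            cochlear_midpoint = np.array([0.0, 0.0, 0.0])

        with pytest.raises(DegenerateGeometryError, match="collinear"):
            compute_alignment_exact(Collinear())


class TestApplyTransform:
    def test_identity_no_expansion_preserves_voxels(self, phantom):
        volume = phantom[0]
        out = apply_transform(volume, RigidTransform(np.eye(3), np.zeros(3)))
        np.testing.assert_allclose(out.voxels, volume.voxels, atol=1e-6)

    def test_pitch_with_expand_z_preserves_head_content(self, phantom):
        volume, lm, _ = phantom
        t = RigidTransform(rotation_x(30.0), lm.cochlear_midpoint)
        out = apply_transform(volume, t, expand_z=True)
        assert out.shape[0] == volume.shape[0] and out.shape[1] == volume.shape[1]
        assert out.shape[2] > volume.shape[2]
        before = (volume.voxels > -200).sum()
        after = (out.voxels > -200).sum()
        assert abs(after - before) / before <= 0.02

    def test_expanded_voxels_take_fill_value(self, phantom):
        volume, lm, _ = phantom
        t = RigidTransform(rotation_x(20.0), lm.cochlear_midpoint)
        out = apply_transform(volume, t, expand_z=True, fill_value=-1024.0)
        assert np.all(out.voxels[:, :, 0] == -1024.0)


class TestTransformPoints:
    def test_identity(self):
        pts = np.array([[1.0, 2, 3], [-4, 5, -6]])
        t = RigidTransform(np.eye(3), np.zeros(3))
        np.testing.assert_array_equal(transform_points(pts, t), pts)

    def test_round_trip_and_rigidity(self):
        rng = np.random.default_rng(16)
        pts = rng.normal(scale=50, size=(10, 3))
        q = rotation_y(31.0) @ rotation_x(-7.0) @ rotation_z(105.0)
        t = RigidTransform(q, center=np.array([5.0, -3.0, 8.0]))
        fwd = transform_points(pts, t)
        np.testing.assert_allclose(transform_points(fwd, t.inverse()), pts, atol=1e-9)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(fwd[:, None] - fwd[None, :], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestAlignVolume:
    def test_exact_mode_zero_deviation_analytically(self, phantom):
        volume, lm, _ = phantom
        rotated, moved, _ = apply_misalignment(
            volume, lm, MisalignmentSpec(yaw_deg=20.0, pitch_deg=15.0, roll_deg=10.0)
        )
        _, aligned_lm, _ = align_volume(rotated, moved, mode="exact")
        dev = cochlear_deviation(aligned_lm)
        assert dev.y_dev_mm <= 1e-9
        assert dev.z_dev_mm <= 1e-9

    def test_sequential_mode_bounded_residual_and_zero_z(self, phantom):
        volume, lm, _ = phantom
        rotated, moved, _ = apply_misalignment(
            volume, lm, MisalignmentSpec(yaw_deg=20.0, pitch_deg=15.0, roll_deg=10.0)
        )
        aligned, aligned_lm, angles = align_volume(rotated, moved, mode="sequential")
        dev = cochlear_deviation(aligned_lm)
        assert dev.z_dev_mm <= 1e-9
        after_yaw = transform_points(
            moved.as_array(), RigidTransform(rotation_z(angles.yaw_deg), angles.center)
        )
        dz = after_yaw[1, 2] - after_yaw[0, 2]
        bound = abs(dz * np.sin(np.radians(angles.pitch_deg))) + 1e-9
        assert dev.y_dev_mm <= bound

    def test_sagittal_offset_tilts_result(self, phantom):
        volume, lm, _ = phantom
        _, lm_plain, _ = align_volume(volume, lm, mode="exact", expand_z=False)
        _, lm_offset, _ = align_volume(
            volume, lm, mode="exact", expand_z=False, sagittal_offset_deg=5.0
        )
        dz = lm_offset.nasal_bridge[2] - lm_offset.right_cochlea[2]
        assert abs(dz) > 1.0  # nb lifted off the cochlear plane by the offset
        assert cochlear_deviation(lm_offset).y_dev_mm <= 1e-9


class TestDecomposeRotation:
    def test_round_trip_random_rotations(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            yaw, roll = rng.uniform(-89, 89, size=2)
            pitch = rng.uniform(-79, 79)
            m = rotation_y(roll) @ rotation_x(pitch) @ rotation_z(yaw)
            y2, p2, r2 = decompose_rotation(m)
            m2 = rotation_y(r2) @ rotation_x(p2) @ rotation_z(y2)
            np.testing.assert_allclose(m2, m, atol=1e-9)
            assert (y2, p2, r2) == pytest.approx((yaw, pitch, roll), abs=1e-9)

    def test_gimbal_adjacent_rejected(self):
        with pytest.raises(DegenerateGeometryError, match="gimbal"):
            decompose_rotation(rotation_x(90.0))
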