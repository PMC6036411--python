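"""Rigid-transform construction, inversion and error metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation as ScipyRotation

from conftest import random_rotation
from regqa.exceptions import DirectionMismatchError, InvalidShiftError
from regqa.transforms import (
    Direction,
    HomogeneousTransform,
    PatientShift,
    RotationSpec,
    ShiftedRole,
    axis_misalignment,
    build_nominal_transform,
    compose_rotations,
    error_at_point,
    expected_translation,
    half_voxel_check,
    invert_transform,
    patient_shift_to_dicom,
    rotation_about_axis,
    rotation_axis,
    transform_point,
    translation_errors,
)

angles = st.floats(min_value=-179.999, max_value=180.0, allow_nan=False)


class TestPatientShift:
    @pytest.mark.parametrize(
        "components, expected",
        [
            ((((10, "Lt"), (5, "Ant"), (15, "Sup"))), (10, -5, 15)),
            ((((0, "Lt"), (0, "Ant"), (0, "Sup"))), (0, 0, 0)),
            ((((3, "Rt"), (5, "Post"), (12, "Inf"))), (-3, 5, -12)),
            ((((12, "Superior"), (3, "right"), (5, "posterior"))), (-3, 5, 12)),
        ],
    )
    def test_patient_directions_map_to_lps(self, components, expected):
        shift = PatientShift(components)
        assert patient_shift_to_dicom(shift) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "components",
        [
            (((10, "Lt"), (5, "Rt"), (15, "Sup"))),  # duplicate axis
            (((10, "Lt"), (5, "Ant"))),  # missing axis
            (((10, "Lt"), (5, "Ant"), (15, "Up"))),  # unknown label
        ],
    )
    def test_invalid_shift_rejected(self, components):
        with pytest.raises(InvalidShiftError):
            PatientShift(components)

    def test_expected_translation_table_sign_conventions(self):
        # stationary dataset shifted: reported T is the negated shift
        case1 = PatientShift(((10, "Lt"), (5, "Ant"), (15, "Sup")), ShiftedRole.STATIONARY)
        assert expected_translation(case1) == pytest.approx((-10, 5, -15))
        # moving dataset shifted: signs kept
        case6 = PatientShift(((3, "Lt"), (5, "Ant"), (12, "Sup")), ShiftedRole.MOVING)
        assert expected_translation(case6) == pytest.approx((3, -5, 12))

    def test_expected_translation_flips_sign_under_role_swap(self):
        comps = ((7, "Rt"), (2, "Post"), (9, "Sup"))
        a = expected_translation(PatientShift(comps, ShiftedRole.STATIONARY))
        b = expected_translation(PatientShift(comps, ShiftedRole.MOVING))
        np.testing.assert_allclose(a, -b)

    def test_role_required(self):
        with pytest.raises(InvalidShiftError):
            expected_translation(PatientShift(((1, "Lt"), (2, "Ant"), (3, "Sup"))))


class TestRotations:
    def test_single_axis_layouts(self):
        np.testing.assert_allclose(rotation_about_axis("x", 0), np.eye(3))
        rz = rotation_about_axis("z", 10)
        np.testing.assert_allclose(
            rz, [[0.9848, -0.1736, 0], [0.1736, 0.9848, 0], [0, 0, 1]], atol=5e-5
        )
        # the y matrix puts -sin at row 1, col 3 (transposed vs textbook)
        ry = rotation_about_axis("y", 8)
        assert ry[0, 2] == pytest.approx(-np.sin(np.deg2rad(8)))
        assert ry[2, 0] == pytest.approx(+np.sin(np.deg2rad(8)))

    def test_compose_reproduces_worked_example(self, phantom_rotation):
        r = compose_rotations(phantom_rotation)
        np.testing.assert_allclose(r[1], [0.172, 0.983, 0.062], atol=5e-4)

    def test_compose_against_independent_euler_construction(self, phantom_rotation):
        # Rz Ry_layout(b) Rx == intrinsic z-y-x Euler with the y angle negated
        r = compose_rotations(phantom_rotation)
        ref = ScipyRotation.from_euler(
            "ZYX",
            [phantom_rotation.angle_z, -phantom_rotation.angle_y, phantom_rotation.angle_x],
            degrees=True,
        ).as_matrix()
        np.testing.assert_allclose(r, ref, atol=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(ax=angles, ay=angles, az=angles)
    def test_compose_is_orthonormal(self, ax, ay, az):
        r = compose_rotations(RotationSpec(ax, ay, az))
        np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_compose_orthonormal_over_many_seeded_triples(self, rng):
        triples = rng.uniform(-179.9, 180.0, size=(1000, 3))
        for ax, ay, az in triples:
            r = compose_rotations(RotationSpec(ax, ay, az))
            assert abs(r @ r.T - np.eye(3)).max() < 1e-9
            assert abs(np.linalg.det(r) - 1.0) < 1e-9

    def test_compose_order_option(self, phantom_rotation):
        r_xyz = compose_rotations(phantom_rotation, order="xyz")
        r_zyx = compose_rotations(phantom_rotation, order="zyx")
        assert not np.allclose(r_xyz, r_zyx)

    def test_angle_range_validated(self):
        with pytest.raises(ValueError):
            RotationSpec(angle_x=200.0)


class TestHomogeneousTransform:
    def test_flat_roundtrip_lossless(self, rng):
        t = HomogeneousTransform(random_rotation(rng), rng.normal(size=3) * 20)
        t2 = HomogeneousTransform.from_flat(t.to_flat())
        assert np.array_equal(t.matrix, t2.matrix)

    def test_bottom_row_enforced(self):
        m = np.eye(4)
        m[3, 0] = 1e-6
        with pytest.raises(ValueError):
            HomogeneousTransform.from_matrix(m)

    def test_nominal_build_places_shift_in_translation(self, phantom_rotation, phantom_shift):
        t = build_nominal_transform(phantom_rotation, phantom_shift)
        np.testing.assert_allclose(t.translation, [5, -15, 20])
        assert t.direction is Direction.MOVING_TO_STATIONARY

    def test_nominal_build_zero_is_identity(self):
        t = build_nominal_transform(RotationSpec(), PatientShift.zero())
        np.testing.assert_allclose(t.matrix, np.eye(4))

    def test_pure_translation_build(self):
        shift = PatientShift(((10, "Lt"), (5, "Ant"), (15, "Sup")))
        t = build_nominal_transform(RotationSpec(), shift)
        np.testing.assert_allclose(t.rotation, np.eye(3))
        np.testing.assert_allclose(t.translation, [10, -5, 15])

    def test_inverse_of_worked_example(self, phantom_rotation, phantom_shift):
        t = build_nominal_transform(phantom_rotation, phantom_shift)
        inv = invert_transform(t)
        np.testing.assert_allclose(inv.translation, [-5.07, 17.29, -18.06], atol=0.05)
        np.testing.assert_allclose(inv.rotation, t.rotation.T, atol=1e-12)
        assert inv.direction is Direction.TARGET_TO_MOVING

    def test_inverse_involution_and_point_roundtrip(self, rng):
        for _ in range(20):
            t = HomogeneousTransform(random_rotation(rng), rng.normal(size=3) * 50)
            np.testing.assert_allclose(
                invert_transform(invert_transform(t)).matrix, t.matrix, atol=1e-9
            )
            p = rng.normal(size=3) * 100
            q = transform_point(invert_transform(t), transform_point(t, p))
            np.testing.assert_allclose(q, p, atol=1e-9)

    def test_pure_translation_inverse_flips_sign(self):
        t = HomogeneousTransform(np.eye(3), [3, -5, 12])
        np.testing.assert_allclose(invert_transform(t).translation, [-3, 5, -12])

    def test_transform_point_examples(self, phantom_rotation, phantom_shift):
        assert transform_point(HomogeneousTransform.identity(), [1, 2, 3]) == pytest.approx(
            [1, 2, 3]
        )
        t = build_nominal_transform(phantom_rotation, phantom_shift)
        np.testing.assert_allclose(transform_point(t, [0, 0, 0]), [5, -15, 20])


class TestTranslationErrors:
    def test_zero_and_known_errors(self):
        rep = HomogeneousTransform(np.eye(3), [-10, 5, -15], Direction.TARGET_TO_MOVING)
        np.testing.assert_allclose(translation_errors(rep, [-10, 5, -15]), [0, 0, 0])
        rep2 = HomogeneousTransform(np.eye(3), [-8.7, 5.0, -15.0], Direction.TARGET_TO_MOVING)
        np.testing.assert_allclose(translation_errors(rep2, [-10, 5, -15]), [1.3, 0, 0])

    def test_direction_mismatch_rejected(self):
        rep = HomogeneousTransform(np.eye(3), [1, 2, 3], Direction.MOVING_TO_STATIONARY)
        with pytest.raises(DirectionMismatchError):
            translation_errors(rep, [1, 2, 3])

    def test_injected_perturbation_recovered_exactly(self, rng):
        for _ in range(20):
            known = rng.normal(size=3) * 20
            delta = rng.normal(size=3) * 2
            rep = HomogeneousTransform(np.eye(3), known + delta, Direction.TARGET_TO_MOVING)
            np.testing.assert_allclose(translation_errors(rep, known), delta, atol=1e-12)

    def test_error_at_origin_equals_translation_difference(self, phantom_rotation, phantom_shift):
        nominal = invert_transform(build_nominal_transform(phantom_rotation, phantom_shift))
        reported = HomogeneousTransform(
            nominal.rotation, nominal.translation + [1.3, 0, 0], nominal.direction
        )
        np.testing.assert_allclose(error_at_point(nominal, reported), [-1.3, 0, 0], atol=1e-12)
        # away from the origin, rotation differences contribute
        tilted = HomogeneousTransform(
            compose_rotations(RotationSpec(0, 0, 1)) @ nominal.rotation,
            nominal.translation,
            nominal.direction,
        )
        assert np.linalg.norm(error_at_point(nominal, tilted, [100, 0, 0])) > 1.0


class TestRotationAxis:
    def test_z_axis_rotation(self):
        ax = rotation_axis(rotation_about_axis("z", 10))
        np.testing.assert_allclose(ax.vector, [0, 0, 1], atol=1e-9)
        assert ax.angle_deg == pytest.approx(10.0)
        assert not ax.degenerate

    def test_worked_example_axis_magnitudes(self, phantom_rotation, phantom_shift):
        inv = invert_transform(build_nominal_transform(phantom_rotation, phantom_shift))
        ax = rotation_axis(inv.rotation)
        np.testing.assert_allclose(np.abs(ax.vector), [0.3165, 0.6251, 0.7135], atol=0.005)

    def test_axis_is_fixed_by_rotation(self, rng):
        for _ in range(50):
            r = random_rotation(rng)
            ax = rotation_axis(r)
            if ax.degenerate or ax.angle_deg < 0.1:
                continue
            np.testing.assert_allclose(r @ ax.vector, ax.vector, atol=1e-9)

    def test_agrees_with_skew_part_axis(self, rng):
        for _ in range(20):
            r = random_rotation(rng)
            ax = rotation_axis(r)
            if ax.degenerate or not (1.0 < ax.angle_deg < 179.0):
                continue
            skew = np.array([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]])
            skew /= np.linalg.norm(skew)
            assert min(
                np.abs(skew - ax.vector).max(), np.abs(skew + ax.vector).max()
            ) < 1e-9

    def test_identity_is_degenerate(self):
        ax = rotation_axis(np.eye(3))
        assert ax.degenerate

    def test_sign_canonicalization(self, rng):
        for _ in range(20):
            r = random_rotation(rng)
            ax = rotation_axis(r)
            if ax.degenerate:
                continue
            assert ax.vector[np.argmax(np.abs(ax.vector))] > 0


class TestAxisMisalignment:
    def test_equal_and_opposite_axes_give_zero(self):
        u = np.array([0.0, 0.0, 1.0])
        assert axis_misalignment(u, u) == pytest.approx(0.0)
        assert axis_misalignment(u, -u) == pytest.approx(0.0)

    def test_one_degree_construction(self):
        v = np.array([0.0, np.sin(np.deg2rad(1)), np.cos(np.deg2rad(1))])
        assert axis_misalignment([0, 0, 1], v) == pytest.approx(1.0, abs=1e-9)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            axis_misalignment([0, 0, 0], [0, 0, 1])

    def test_degenerate_axis_reports_zero_with_warning(self):
        ax = rotation_axis(np.eye(3))
        with pytest.warns(UserWarning):
            assert axis_misalignment(ax, [0, 0, 1]) == 0.0

    def test_result_range(self, rng):
        for _ in range(50):
            u = rng.normal(size=3)
            v = rng.normal(size=3)
            m = axis_misalignment(u, v)
            assert 0.0 <= m <= 90.0


class TestHalfVoxelCheck:
    def test_examples(self):
        assert half_voxel_check([0, 0, 0], [1, 1, 1]).all()
        np.testing.assert_array_equal(
            half_voxel_check([1.3, 1.3, 0.1], [0.7, 0.7, 3.0]), [False, False, True]
        )
        # boundary is inclusive
        assert half_voxel_check([0.35, 0.35, 1.5], [0.7, 0.7, 3.0]).all()

    def test_positive_voxel_required(self):
        with pytest.raises(ValueError):
            half_voxel_check([0, 0, 0], [1, 0, 1])
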