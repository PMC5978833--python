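"""Quaternion -> rotation -> spherical-coordinate chain correctness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reachmap import (
    QuaternionSample,
    quat_to_rotmat,
    relative_rotation,
    rotate_point,
    stream_to_poses,
    to_spherical,
)
from reachmap.errors import (
    DegenerateDirectionError,
    EmptyStreamError,
    InvalidRotationError,
    InvalidSampleError,
    NonMonotoneTimeError,
)
from reachmap.simulate import spherical_to_quaternion

from .conftest import IDENTITY_REFERENCE, make_sample, random_unit_quaternions, sandwich_rotate

SQ2 = np.sqrt(2.0) / 2.0


def rotmat_about(axis, degrees):
    """Independent axis-angle rotation-matrix oracle (Rodrigues)."""
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    th = np.radians(degrees)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


class TestQuatToRotmat:
    def test_identity_quaternion(self):
        assert np.allclose(quat_to_rotmat((1, 0, 0, 0)), np.eye(3))

    def test_quarter_turn_about_x(self):
        R = quat_to_rotmat((SQ2, SQ2, 0, 0))
        assert np.allclose(R @ [0, 0, 1], [0, -1, 0], atol=1e-12)
        assert np.allclose(R, rotmat_about([1, 0, 0], 90), atol=1e-12)

    def test_agrees_with_sandwich_product_oracle(self):
        rng = np.random.default_rng(42)
        quats = random_unit_quaternions(1000, rng)
        vecs = rng.normal(size=(1000, 3))
        for q, v in zip(quats, vecs):
            R = quat_to_rotmat(tuple(q))
            assert np.allclose(R @ v, sandwich_rotate(q, v), atol=1e-9)

    def test_agrees_with_scipy_rotation(self):
        scipy_rot = pytest.importorskip("scipy.spatial.transform").Rotation
        rng = np.random.default_rng(3)
        for q in random_unit_quaternions(50, rng):
            R = quat_to_rotmat(tuple(q))
            # scipy stores quaternions (x, y, z, w)
            R_ref = scipy_rot.from_quat(np.roll(q, -1)).as_matrix()
            assert np.allclose(R, R_ref, atol=1e-12)

    def test_bad_norm_raises_with_timestamp(self):
        with pytest.raises(InvalidSampleError, match="t=1.5"):
            QuaternionSample.create(1.5, 1.0, 0.5, 0.0, 0.0)

    def test_slightly_off_norm_is_renormalized(self):
        s = QuaternionSample.create(0.0, 1.0 + 5e-4, 0.0, 0.0, 0.0)
        assert np.isclose(np.linalg.norm(s.elements), 1.0, atol=1e-12)

    def test_negative_qw_canonicalized(self):
        s = QuaternionSample.create(0.0, -SQ2, SQ2, 0.0, 0.0)
        assert s.qw >= 0


class TestRelativeRotation:
    def test_neutral_pose_maps_to_identity(self):
        R = quat_to_rotmat((SQ2, 0, SQ2, 0))
        assert np.allclose(relative_rotation(R, R), np.eye(3), atol=1e-12)

    def test_identity_reference_returns_input(self):
        R = rotmat_about([0, 1, 0], 37.0)
        assert np.allclose(relative_rotation(R, np.eye(3)), R)

    def test_composition_about_common_axis(self):
        R0 = rotmat_about([0, 0, 1], 30.0)
        R = rotmat_about([0, 0, 1], 50.0)
        assert np.allclose(relative_rotation(R, R0), rotmat_about([0, 0, 1], 20.0), atol=1e-12)

    def test_compose_back_recovers_original(self):
        rng = np.random.default_rng(11)
        for q, q0 in zip(random_unit_quaternions(20, rng), random_unit_quaternions(20, rng)):
            R, R0 = quat_to_rotmat(tuple(q)), quat_to_rotmat(tuple(q0))
            assert np.allclose(R0 @ relative_rotation(R, R0), R, atol=1e-9)

    def test_non_orthonormal_input_rejected(self):
        with pytest.raises(InvalidRotationError):
            relative_rotation(np.eye(3) * 2.0, np.eye(3))


class TestRotatePoint:
    def test_identity_preserves_point(self):
        assert np.allclose(rotate_point(np.eye(3), [1.0, 2.0, 3.0]), [1, 2, 3])

    def test_quarter_turn_example(self):
        R = quat_to_rotmat((SQ2, SQ2, 0, 0))
        assert np.allclose(rotate_point(R, [0, 0, 1]), [0, -1, 0], atol=1e-12)

    def test_isometry(self):
        rng = np.random.default_rng(5)
        for q in random_unit_quaternions(25, rng):
            p = rng.normal(size=3)
            out = rotate_point(quat_to_rotmat(tuple(q)), p)
            assert np.isclose(np.linalg.norm(out), np.linalg.norm(p), atol=1e-9)

    def test_zero_point_rejected(self):
        with pytest.raises(DegenerateDirectionError):
            rotate_point(np.eye(3), [0.0, 0.0, 0.0])


class TestToSpherical:
    @pytest.mark.parametrize(
        "point, alpha, beta, r",
        [
            ((0, 0, 1), 0.0, 0.0, 1.0),  # neutral: arm at rest
            ((1, 0, 0), 0.0, 90.0, 1.0),  # anterior horizontal
            ((0, 1, 0), 90.0, 90.0, 1.0),  # lateral horizontal
            ((1, 1, np.sqrt(2)), 45.0, 45.0, 2.0),
            ((3, 3, 3 * np.sqrt(2)), 45.0, 45.0, 6.0),
            ((-1, 0, 0), 180.0, 90.0, 1.0),  # posterior maps into (-180, 180]
        ],
    )
    def test_known_conversions(self, point, alpha, beta, r):
        pose = to_spherical(point)
        assert pose.alpha == pytest.approx(alpha, abs=1e-12)
        assert pose.beta == pytest.approx(beta, abs=1e-12)
        assert pose.r == pytest.approx(r, abs=1e-12)

    def test_zero_norm_rejected(self):
        with pytest.raises(DegenerateDirectionError):
            to_spherical((0.0, 0.0, 0.0))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        alpha=st.floats(min_value=-179.999, max_value=180.0),
        beta=st.floats(min_value=0.001, max_value=179.999),
    )
    def test_spherical_cartesian_round_trip(self, alpha, beta):
        a, b = np.radians(alpha), np.radians(beta)
        p = (np.sin(b) * np.cos(a), np.sin(b) * np.sin(a), np.cos(b))
        pose = to_spherical(p)
        assert pose.beta == pytest.approx(beta, abs=1e-9)
        assert pose.alpha == pytest.approx(alpha, abs=1e-9)


class TestStreamToPoses:
    def test_reference_only_stream_is_neutral(self):
        ref = make_sample(SQ2, 0, SQ2, 0)
        trace = stream_to_poses([ref], ref)
        assert trace.beta[0] == pytest.approx(0.0, abs=1e-9)

    def test_empty_stream_rejected(self):
        with pytest.raises(EmptyStreamError):
            stream_to_poses([], make_sample(1, 0, 0, 0))

    def test_non_monotone_timestamps_rejected(self):
        s = [make_sample(1, 0, 0, 0, t=0.0), make_sample(1, 0, 0, 0, t=0.0)]
        with pytest.raises(NonMonotoneTimeError):
            stream_to_poses(s, s[0])

    def test_outputs_satisfy_pose_invariants(self):
        rng = np.random.default_rng(9)
        quats = random_unit_quaternions(200, rng)
        stream = [make_sample(*q, t=i * 0.01) for i, q in enumerate(quats)]
        trace = stream_to_poses(stream, make_sample(1, 0, 0, 0))
        assert np.all((trace.beta >= 0) & (trace.beta <= 180))
        assert np.all((trace.alpha > -180) & (trace.alpha <= 180))
        assert np.all(trace.r > 0)

    def test_relative_to_reference_orientation(self):
        """A stream equal to the reference composed with a known rotation
        recovers that rotation's spherical image."""
        ref_q = (SQ2, 0, 0, SQ2)  # arbitrary non-identity mounting pose
        move = np.array(spherical_to_quaternion(25.0, 70.0))
        from .conftest import quat_multiply

        composed = quat_multiply(np.array(ref_q, dtype=float), move)
        stream = [make_sample(*composed, t=0.0)]
        trace = stream_to_poses(stream, make_sample(*ref_q))
        assert trace.alpha[0] == pytest.approx(25.0, abs=1e-9)
        assert trace.beta[0] == pytest.approx(70.0, abs=1e-9)


class TestGimbalLockFreedom:
    @pytest.mark.parametrize(
        "trajectory",
        [
            # horizontal great circle: crosses alpha = +/-180 at beta = 90
            [(a, 90.0) for a in np.arange(-179.0, 181.0, 1.0)],
            # meridian over the pole: beta rises through 90 up to 180 and back
            [(0.0, b) for b in np.arange(1.0, 181.0, 1.0)]
            + [(180.0, b) for b in np.arange(179.0, 0.0, -1.0)],
        ],
        ids=["horizontal-circle", "meridian-over-pole"],
    )
    def test_great_circle_sweep_has_no_discontinuity(self, trajectory):
        """Tracking a continuous 1-degree-step sweep never jumps more than
        the step size in direction space (no gimbal lock)."""
        stream = [
            make_sample(*spherical_to_quaternion(a, b), t=i * 0.01)
            for i, (a, b) in enumerate(trajectory)
        ]
        trace = stream_to_poses(stream, make_sample(1, 0, 0, 0))
        b = np.radians(trace.beta)
        a = np.radians(trace.alpha)
        dirs = np.column_stack([np.sin(b) * np.cos(a), np.sin(b) * np.sin(a), np.cos(b)])
        dots = np.clip(np.sum(dirs[1:] * dirs[:-1], axis=1), -1.0, 1.0)
        steps = np.degrees(np.arccos(dots))
        assert np.max(steps) <= 1.0 + 1e-6
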