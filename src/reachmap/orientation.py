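"""Quaternion and rotation-matrix kinematics for single-IMU arm tracking.

The wearable sensor streams unit quaternions at 100 Hz.  Each sample is
converted to a rotation matrix, expressed relative to the neutral-pose
reference orientation, applied to a fixed arm-direction vector, and the
resulting Cartesian direction is converted to spherical coordinates:
azimuth ``alpha`` (direction of the elevated arm around the vertical
axis) and elevation ``beta`` (angle of the arm from its hanging neutral
direction).  Quaternion/rotation-matrix tracking has no representational
singularity, so the pipeline is free of gimbal lock.

Body-frame convention (right handed):

* ``+z`` along the hanging arm at neutral, so ``beta = 0`` at rest;
* ``+x`` anterior, so the flexion plane is ``alpha = 0``;
* ``+y`` to the subject's lateral side, so ``alpha = +90`` is the
  abduction plane and ``|alpha| -> 180`` is posterior.

Axial rotation of the humerus about its long axis does not change the
arm direction and therefore never appears in the output (this is what
side-steps Codman's paradox).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DegenerateDirectionError,
    EmptyStreamError,
    InvalidRotationError,
    InvalidSampleError,
    NonMonotoneTimeError,
)

#: Maximum allowed deviation of a quaternion norm from 1 before the sample
#: is rejected instead of renormalized.
NORM_TOLERANCE = 1e-3

#: Orthonormality tolerance for rotation-matrix validation.
ROTATION_TOLERANCE = 1e-6


@dataclass(frozen=True)
class QuaternionSample:
    """One timestamped unit-quaternion reading ``q = qw + i qx + j qy + k qz``.

    ``t`` is seconds since stream start.  The stored elements are
    canonicalized: renormalized to unit length and sign-flipped so that
    ``qw >= 0`` (a quaternion and its negation encode the same rotation;
    the canonical sign makes round trips deterministic).
    """

    t: float
    qw: float
    qx: float
    qy: float
    qz: float

    @classmethod
    def create(
        cls,
        t: float,
        qw: float,
        qx: float,
        qy: float,
        qz: float,
        tol: float = NORM_TOLERANCE,
    ) -> "QuaternionSample":
        """Validate, renormalize and canonicalize a raw reading."""
        norm = float(np.sqrt(qw * qw + qx * qx + qy * qy + qz * qz))
        if abs(norm - 1.0) > tol:
            raise InvalidSampleError(t, norm, tol)
        qw, qx, qy, qz = (c / norm for c in (qw, qx, qy, qz))
        if qw < 0:
            qw, qx, qy, qz = -qw, -qx, -qy, -qz
        return cls(float(t), qw, qx, qy, qz)

    @property
    def elements(self) -> np.ndarray:
        return np.array([self.qw, self.qx, self.qy, self.qz])


@dataclass(frozen=True)
class SphericalPose:
    """Arm direction in spherical coordinates.

    ``alpha``: azimuth in degrees, in ``(-180, 180]``;
    ``beta``: elevation in degrees, in ``[0, 180]``;
    ``r``: radial distance in the length units of the input point.
    """

    alpha: float
    beta: float
    r: float


def quat_to_rotmat(q: QuaternionSample | Sequence[float]) -> np.ndarray:
    """Convert a unit quaternion to its 3x3 rotation matrix.

    Accepts a :class:`QuaternionSample` or a raw ``(qw, qx, qy, qz)``
    sequence (validated on the fly).  The returned matrix ``R`` rotates a
    body-frame vector into the world frame: ``v_world = R @ v_body``,
    identical to the quaternion sandwich product ``q v q⁻¹``.
    """
    if not isinstance(q, QuaternionSample):
        q = QuaternionSample.create(0.0, *q)
    qw, qx, qy, qz = q.qw, q.qx, q.qy, q.qz
    return np.array(
        [
            [
                qw * qw + qx * qx - qy * qy - qz * qz,
                2 * (qx * qy - qw * qz),
                2 * (qx * qz + qw * qy),
            ],
            [
                2 * (qx * qy + qw * qz),
                qw * qw - qx * qx + qy * qy - qz * qz,
                2 * (qy * qz - qw * qx),
            ],
            [
                2 * (qx * qz - qw * qy),
                2 * (qy * qz + qw * qx),
                qw * qw - qx * qx - qy * qy + qz * qz,
            ],
        ]
    )


def validate_rotation(R: np.ndarray, tol: float = ROTATION_TOLERANCE) -> np.ndarray:
    """Check orthonormality (RᵀR = I) and det = +1; return R as float array."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise InvalidRotationError(f"expected a 3x3 matrix, got shape {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=max(tol, 1e-9)):
        raise InvalidRotationError("matrix is not orthonormal")
    if abs(np.linalg.det(R) - 1.0) > max(tol, 1e-9):
        raise InvalidRotationError("matrix determinant is not +1 (improper rotation)")
    return R


def relative_rotation(R: np.ndarray, R0: np.ndarray) -> np.ndarray:
    """Orientation ``R`` expressed relative to the reference pose ``R0``.

    Returns ``R0⁻¹ R``; the inverse is computed as the transpose, which is
    exact for rotation matrices.
    """
    R = validate_rotation(R)
    R0 = validate_rotation(R0)
    return R0.T @ R


def rotate_point(R: np.ndarray, p0: Sequence[float]) -> np.ndarray:
    """Rotate the arm-fixed point ``p0`` by ``R``; norm is preserved."""
    R = validate_rotation(R)
    p0 = np.asarray(p0, dtype=float)
    if not np.all(np.isfinite(p0)) or np.linalg.norm(p0) == 0.0:
        raise DegenerateDirectionError("point must be finite with non-zero norm")
    return R @ p0


def to_spherical(p: Sequence[float]) -> SphericalPose:
    """Cartesian arm direction -> spherical pose.

    ``r = |p|``; ``beta = arccos(z / r)``; ``alpha = atan2(y, x)``.  The
    azimuth uses the full-quadrant two-argument arctangent so posterior
    directions (|alpha| > 90) are represented; it reduces to ``atan(y/x)``
    in the anterior half-space.  Angles are returned in degrees.
    """
    x, y, z = (float(c) for c in np.asarray(p, dtype=float))
    r = float(np.sqrt(x * x + y * y + z * z))
    if r == 0.0 or not np.isfinite(r):
        raise DegenerateDirectionError("cannot convert a zero-norm point")
    beta = float(np.degrees(np.arccos(np.clip(z / r, -1.0, 1.0))))
    alpha = float(np.degrees(np.arctan2(y, x)))
    if alpha <= -180.0:  # map the branch point into (-180, 180]
        alpha = 180.0
    return SphericalPose(alpha=alpha, beta=beta, r=r)


@dataclass(frozen=True)
class PoseTrace:
    """A time series of spherical arm poses (vectorized SphericalPose)."""

    t: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    r: np.ndarray

    def __len__(self) -> int:
        return len(self.t)


def _quats_to_matrices(q: np.ndarray) -> np.ndarray:
    """Vectorized quaternion -> rotation matrix; q is (n, 4)."""
    qw, qx, qy, qz = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    R = np.empty((len(q), 3, 3))
    R[:, 0, 0] = qw * qw + qx * qx - qy * qy - qz * qz
    R[:, 0, 1] = 2 * (qx * qy - qw * qz)
    R[:, 0, 2] = 2 * (qx * qz + qw * qy)
    R[:, 1, 0] = 2 * (qx * qy + qw * qz)
    R[:, 1, 1] = qw * qw - qx * qx + qy * qy - qz * qz
    R[:, 1, 2] = 2 * (qy * qz - qw * qx)
    R[:, 2, 0] = 2 * (qx * qz - qw * qy)
    R[:, 2, 1] = 2 * (qy * qz + qw * qx)
    R[:, 2, 2] = qw * qw - qx * qx - qy * qy + qz * qz
    return R


def stream_to_poses(
    stream: Iterable[QuaternionSample],
    reference: QuaternionSample,
    arm_direction: Sequence[float] = (0.0, 0.0, 1.0),
) -> PoseTrace:
    """Convert a quaternion stream to reference-relative spherical poses.

    For each sample the chain is: quaternion -> rotation matrix ->
    rotation relative to the neutral-pose reference -> image of the
    arm-direction vector -> spherical coordinates.  ``arm_direction``
    defaults to the unit ``+z`` axis (the hanging arm at neutral); only
    its direction matters, so ``r`` is constant along the trace.
    """
    samples = list(stream)
    if not samples:
        raise EmptyStreamError("quaternion stream is empty")
    t = np.array([s.t for s in samples])
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise NonMonotoneTimeError("timestamps must be strictly increasing")
    d = np.asarray(arm_direction, dtype=float)
    if np.linalg.norm(d) == 0.0:
        raise DegenerateDirectionError("arm_direction must have non-zero norm")

    R0 = quat_to_rotmat(reference)
    Rs = _quats_to_matrices(np.array([s.elements for s in samples]))
    # p_i = R0ᵀ R_i d, vectorized over samples
    p = (Rs @ d) @ R0  # (n,3) @ (3,3): row_i = (R_i d)ᵀ R0 = (R0ᵀ R_i d)ᵀ
    r = np.linalg.norm(p, axis=1)
    beta = np.degrees(np.arccos(np.clip(p[:, 2] / r, -1.0, 1.0)))
    alpha = np.degrees(np.arctan2(p[:, 1], p[:, 0]))
    alpha[alpha <= -180.0] = 180.0
    return PoseTrace(t=t, alpha=alpha, beta=beta, r=r)
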