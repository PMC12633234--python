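"""Rigid-body poses on SO(3): unit quaternions, zyz Euler angles, translations.

A particle pose is an orientation ``R`` together with an in-plane translation
``t = (tx, ty, 0)`` in Å.  All orientation parametrizations convert to a unit
quaternion :class:`Rotation`, the common currency used by the projection and
image-formation modules.

Euler angles follow the standard single-particle convention: ``phi`` rotates
about z first, then ``theta`` about y, then ``psi`` about z again, all as
*active* rotations of body-frame vectors into the lab frame, i.e. the matrix
is ``Rz(psi) @ Ry(theta) @ Rz(phi)``.  Angles are degrees at this interface
and radians internally.  ``q`` and ``-q`` denote the same rotation and are
treated as equal everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Rotation",
    "EulerPose",
    "QuaternionPose",
    "rotation_from_euler",
    "apply_rotation",
    "invert_rotation",
    "compose_rotations",
    "euler_from_rotation",
]

_NORM_TOL = 1e-9


def _quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ]
    )


@dataclass(frozen=True)
class Rotation:
    """A rotation in SO(3) stored as a scalar-first unit quaternion (w, x, y, z)."""

    q: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if q.shape != (4,) or not np.all(np.isfinite(q)):
            raise ValueError("quaternion must be 4 finite numbers (w, x, y, z)")
        norm = np.linalg.norm(q)
        if norm == 0.0:
            raise ValueError("zero quaternion does not define a rotation")
        object.__setattr__(self, "q", q / norm)
        self.q.setflags(write=False)

    @classmethod
    def identity(cls) -> "Rotation":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]))

    @classmethod
    def from_axis_angle(cls, axis, angle_rad: float) -> "Rotation":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        half = 0.5 * angle_rad
        return cls(np.concatenate([[np.cos(half)], np.sin(half) * axis]))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "Rotation":
        """Shepperd's method: the numerically largest quaternion component pivots."""
        m = np.asarray(m, dtype=float)
        tr = np.trace(m)
        choices = [tr, m[0, 0], m[1, 1], m[2, 2]]
        i = int(np.argmax(choices))
        if i == 0:
            s = np.sqrt(tr + 1.0) * 2.0
            q = [0.25 * s, (m[2, 1] - m[1, 2]) / s, (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s]
        elif i == 1:
            s = np.sqrt(1.0 + m[0, 0] - m[1, 1] - m[2, 2]) * 2.0
            q = [(m[2, 1] - m[1, 2]) / s, 0.25 * s, (m[0, 1] + m[1, 0]) / s, (m[0, 2] + m[2, 0]) / s]
        elif i == 2:
            s = np.sqrt(1.0 + m[1, 1] - m[0, 0] - m[2, 2]) * 2.0
            q = [(m[0, 2] - m[2, 0]) / s, (m[0, 1] + m[1, 0]) / s, 0.25 * s, (m[1, 2] + m[2, 1]) / s]
        else:
            s = np.sqrt(1.0 + m[2, 2] - m[0, 0] - m[1, 1]) * 2.0
            q = [(m[1, 0] - m[0, 1]) / s, (m[0, 2] + m[2, 0]) / s, (m[1, 2] + m[2, 1]) / s, 0.25 * s]
        return cls(np.array(q))

    def as_matrix(self) -> np.ndarray:
        w, x, y, z = self.q
        return np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )

    def apply(self, v: np.ndarray) -> np.ndarray:
        """Rotate vectors (shape (..., 3)) by the quaternion sandwich q v q*."""
        v = np.asarray(v, dtype=float)
        w = self.q[0]
        u = self.q[1:]
        # q v q* expanded: v + 2 w (u x v) + 2 u x (u x v)
        uv = np.cross(u, v)
        return v + 2.0 * (w * uv + np.cross(u, uv))

    def inverse(self) -> "Rotation":
        return Rotation(self.q * np.array([1.0, -1.0, -1.0, -1.0]))

    def compose(self, other: "Rotation") -> "Rotation":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return Rotation(_quat_multiply(self.q, other.q))

    def __matmul__(self, other: "Rotation") -> "Rotation":
        return self.compose(other)

    def isclose(self, other: "Rotation", atol: float = 1e-9) -> bool:
        """Equality up to the q ↔ −q double cover."""
        return bool(
            np.allclose(self.q, other.q, atol=atol) or np.allclose(self.q, -other.q, atol=atol)
        )


def _check_finite_angles(*angles: float) -> None:
    if not all(np.isfinite(a) for a in angles):
        raise ValueError("Euler angles must be finite")


def rotation_from_euler(phi: float, theta: float, psi: float) -> Rotation:
    """Unit quaternion of the active zyz rotation Rz(psi)·Ry(theta)·Rz(phi).

    ``phi`` is applied first (about z), then ``theta`` (about y), then
    ``psi`` (about z).  Angles in degrees.
    """
    _check_finite_angles(phi, theta, psi)
    ez = np.array([0.0, 0.0, 1.0])
    ey = np.array([0.0, 1.0, 0.0])
    qphi = Rotation.from_axis_angle(ez, np.deg2rad(phi))
    qtheta = Rotation.from_axis_angle(ey, np.deg2rad(theta))
    qpsi = Rotation.from_axis_angle(ez, np.deg2rad(psi))
    return qpsi @ qtheta @ qphi


def apply_rotation(r: Rotation, v: np.ndarray) -> np.ndarray:
    return r.apply(v)


def invert_rotation(r: Rotation) -> Rotation:
    return r.inverse()


def compose_rotations(a: Rotation, b: Rotation) -> Rotation:
    return a.compose(b)


def euler_from_rotation(r: Rotation) -> tuple[float, float, float]:
    """Recover (phi, theta, psi) in degrees from a rotation.

    At gimbal lock (theta = 0° or 180°) the decomposition is degenerate; the
    canonical solution with psi = 0 is returned.
    """
    m = r.as_matrix()
    c = np.clip(m[2, 2], -1.0, 1.0)
    theta = np.arccos(c)
    if np.isclose(np.sin(theta), 0.0, atol=1e-9):
        psi = 0.0
        if c > 0:  # theta = 0: m = Rz(psi + phi)
            phi = np.arctan2(m[1, 0], m[0, 0])
        else:  # theta = 180: m = Ry(pi) Rz(phi) with psi = 0
            phi = np.arctan2(m[1, 0], m[1, 1])
    else:
        psi = np.arctan2(m[1, 2], m[0, 2])
        phi = np.arctan2(m[2, 1], -m[2, 0])
    return (float(np.rad2deg(phi)), float(np.rad2deg(theta)), float(np.rad2deg(psi)))


@dataclass(frozen=True)
class EulerPose:
    """Pose from zyz Euler angles (degrees) plus in-plane translation (Å)."""

    phi: float = 0.0
    theta: float = 0.0
    psi: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self):
        _check_finite_angles(self.phi, self.theta, self.psi)
        if not (np.isfinite(self.tx) and np.isfinite(self.ty)):
            raise ValueError("translations must be finite")

    @property
    def rotation(self) -> Rotation:
        return rotation_from_euler(self.phi, self.theta, self.psi)

    @property
    def translation(self) -> tuple[float, float]:
        return (self.tx, self.ty)


@dataclass(frozen=True)
class QuaternionPose:
    """Pose from a unit quaternion (w, x, y, z) plus in-plane translation (Å)."""

    q: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "q", Rotation(self.q).q)
        if not (np.isfinite(self.tx) and np.isfinite(self.ty)):
            raise ValueError("translations must be finite")

    @property
    def rotation(self) -> Rotation:
        return Rotation(self.q)

    @property
    def translation(self) -> tuple[float, float]:
        return (self.tx, self.ty)
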