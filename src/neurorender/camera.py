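"""Spherical-coordinate camera with a quaternion-stored orientation.

The camera orbits a focus point (``center``) at distance ``r``.  Rather
than keeping the polar angles themselves, the pose stores their composed
rotation as a unit quaternion, which also absorbs roll and avoids gimbal
lock under incremental orbiting.  Conventions: at the identity orientation
the camera sits at ``center + r * ez`` looking down ``-z`` with up ``+y``;
``theta`` tilts about the camera-right axis, ``phi`` turns about world-up.

Operations are pure: each returns a new :class:`CameraPose`, re-normalizing
the quaternion so numerical drift never accumulates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Quaternion",
    "CameraPose",
    "quat_from_axis_angle",
    "make_camera",
    "orbit",
    "roll",
    "zoom",
    "pan",
    "view_matrix",
]

_MIN_RADIUS, _MAX_RADIUS = 1e-3, 1e6


@dataclass(frozen=True)
class Quaternion:
    """Unit quaternion ``w + xi + yj + zk`` encoding a 3D rotation."""

    w: float
    x: float
    y: float
    z: float

    @classmethod
    def identity(cls) -> "Quaternion":
        return cls(1.0, 0.0, 0.0, 0.0)

    def normalized(self) -> "Quaternion":
        n = np.sqrt(self.w**2 + self.x**2 + self.y**2 + self.z**2)
        if n == 0:
            raise ValueError("cannot normalize a zero quaternion")
        return Quaternion(self.w / n, self.x / n, self.y / n, self.z / n)

    def conjugate(self) -> "Quaternion":
        return Quaternion(self.w, -self.x, -self.y, -self.z)

    def norm(self) -> float:
        return float(np.sqrt(self.w**2 + self.x**2 + self.y**2 + self.z**2))

    def __mul__(self, o: "Quaternion") -> "Quaternion":
        w1, x1, y1, z1 = self.w, self.x, self.y, self.z
        w2, x2, y2, z2 = o.w, o.x, o.y, o.z
        return Quaternion(
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        )

    def rotate(self, v: np.ndarray) -> np.ndarray:
        """Apply the rotation to a 3-vector (or an (n, 3) stack)."""
        return np.asarray(v, dtype=np.float64) @ self.rotation_matrix().T

    def rotation_matrix(self) -> np.ndarray:
        w, x, y, z = self.w, self.x, self.y, self.z
        return np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> Quaternion:
    """Unit quaternion for a rotation of *angle* radians about *axis*."""
    a = np.asarray(axis, dtype=np.float64).reshape(3)
    n = np.linalg.norm(a)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    a = a / n
    h = 0.5 * angle
    s = np.sin(h)
    return Quaternion(float(np.cos(h)), float(a[0] * s), float(a[1] * s), float(a[2] * s))


@dataclass(frozen=True)
class CameraPose:
    """Focus point, orbit radius (mm) and orientation quaternion."""

    center: np.ndarray
    r: float
    orientation: Quaternion

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=np.float64).reshape(3))
        if self.r <= 0:
            raise ValueError("radius must be positive")

    @property
    def eye(self) -> np.ndarray:
        """World position of the camera."""
        return self.center + self.r * self.orientation.rotate(np.array([0.0, 0.0, 1.0]))

    @property
    def right(self) -> np.ndarray:
        return self.orientation.rotate(np.array([1.0, 0.0, 0.0]))

    @property
    def up(self) -> np.ndarray:
        return self.orientation.rotate(np.array([0.0, 1.0, 0.0]))

    @property
    def view_dir(self) -> np.ndarray:
        """Unit direction the camera looks along (eye → center)."""
        return -self.orientation.rotate(np.array([0.0, 0.0, 1.0]))


def make_camera(center, r: float, theta: float = 0.0, phi: float = 0.0) -> CameraPose:
    """Camera on the sphere of radius *r* around *center* at angles (θ, φ).

    φ turns about world-up (+y); θ then tilts about the turned camera-right
    axis.  θ = φ = 0 places the eye at ``center + r*ez``.
    """
    q_phi = quat_from_axis_angle([0.0, 1.0, 0.0], phi)
    q_theta = quat_from_axis_angle([1.0, 0.0, 0.0], -theta)
    return CameraPose(center=center, r=float(r), orientation=(q_phi * q_theta).normalized())


def orbit(c: CameraPose, d_theta: float, d_phi: float) -> CameraPose:
    """Incrementally orbit: pre-multiply the φ- then θ-increment rotations."""
    q = c.orientation
    if d_theta:
        q = quat_from_axis_angle([1.0, 0.0, 0.0], -d_theta) * q
    if d_phi:
        q = quat_from_axis_angle([0.0, 1.0, 0.0], d_phi) * q
    return replace(c, orientation=q.normalized())


def roll(c: CameraPose, angle: float) -> CameraPose:
    """Rotate about the view axis (two-finger "rotate" gesture)."""
    q = c.orientation * quat_from_axis_angle([0.0, 0.0, 1.0], angle)
    return replace(c, orientation=q.normalized())


def zoom(c: CameraPose, factor: float) -> CameraPose:
    """Divide the orbit radius by *factor* (pinch-out magnifies); clamped."""
    if factor <= 0:
        raise ValueError("zoom factor must be positive")
    r = min(max(c.r / factor, _MIN_RADIUS), _MAX_RADIUS)
    return replace(c, r=r)


def pan(c: CameraPose, dx: float, dy: float) -> CameraPose:
    """Translate the focus point in the camera's right/up plane (mm)."""
    return replace(c, center=c.center + dx * c.right + dy * c.up)


def view_matrix(c: CameraPose) -> np.ndarray:
    """4x4 world → camera look-at transform.

    Camera space: x = right, y = up, z toward the viewer; the eye maps to
    the origin and the focus point to ``(0, 0, -r)``.
    """
    backward = c.orientation.rotate(np.array([0.0, 0.0, 1.0]))
    R = np.stack([c.right, c.up, backward])
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = -R @ c.eye
    return M
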