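"""Rigid-body poses and small rotation helpers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def rotation_from_rotvec(v: np.ndarray) -> np.ndarray:
    """Rotation matrix from a rotation vector (Rodrigues formula).

    Cheap replacement for scipy's Rotation in the hot BD loop.
    """
    v = np.asarray(v, dtype=float)
    theta = np.linalg.norm(v)
    if theta < 1e-12:
        # first-order expansion; adequate below the tolerance
        K = _skew(v)
        return np.eye(3) + K
    axis = v / theta
    K = _skew(axis)
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]],
                     [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via random quaternion)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


@dataclass
class Pose:
    """Rigid transform: x_world = R @ x_body + t."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def copy(self) -> "Pose":
        return Pose(self.rotation.copy(), self.translation.copy())

    @property
    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.rotation))
                    and np.all(np.isfinite(self.translation)))

    @staticmethod
    def identity() -> "Pose":
        return Pose()
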