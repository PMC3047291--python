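"""Core containers shared across the pipeline.

Conventions used throughout the package:

* All lengths are millimetres; intensities are CT units after rescale.
* Volumes are axis-aligned scalar grids indexed ``(i, j, k)`` = ``(x, y, z)``,
  with ``z`` the slice axis.  The world coordinate of voxel centre ``(i, j, k)``
  is ``origin + (i, j, k) * spacing``; a single function
  (:meth:`VoxelVolume.index_to_world`) implements this mapping and every module
  goes through it.
* Rigid transforms are proper rotations plus translations and act as
  ``p -> R @ p + t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GuidefitError",
    "ParameterError",
    "DegenerateGeometryError",
    "VoxelVolume",
    "RigidTransform",
]


class GuidefitError(Exception):
    """Base class for errors raised by this package."""


class ParameterError(GuidefitError, ValueError):
    """A parameter violates a stated invariant."""


class DegenerateGeometryError(GuidefitError, ValueError):
    """Geometry too degenerate for the requested operation."""


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size == 1:
        v = np.repeat(v, 3)
    if v.shape != (3,):
        raise ParameterError(f"{name} must be a scalar or length-3 vector, got {x!r}")
    return v


@dataclass
class VoxelVolume:
    """Axis-aligned scalar volume with physical spacing and origin (mm).

    ``data[i, j, k]`` is the intensity at world point
    ``origin + (i, j, k) * spacing``; ``k`` runs along the slice axis.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ParameterError(f"volume data must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 2:
            raise ParameterError(f"all volume dims must be >= 2, got {self.data.shape}")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if not np.all(self.spacing > 0):
            raise ParameterError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_vec3(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_world(self, indices) -> np.ndarray:
        """Map (fractional) voxel indices to world mm coordinates.

        This is the single voxel→world convention shared by every module.
        """
        idx = np.asarray(indices, dtype=float)
        return self.origin + idx * self.spacing

    def world_to_index(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - self.origin) / self.spacing

    def copy_with(self, data: np.ndarray) -> "VoxelVolume":
        return VoxelVolume(data=data, spacing=self.spacing.copy(), origin=self.origin.copy())


_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> rotation @ p + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ParameterError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ParameterError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ParameterError("rotation axis must be nonzero")
        axis = axis / n
        a = np.deg2rad(angle_deg)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
        # re-orthonormalise to keep the invariant tight
        u, _, vt = np.linalg.svd(R)
        R = u @ vt
        return cls(R, np.asarray(translation, dtype=float))

    def apply(self, points) -> np.ndarray:
        """Apply to an (N, 3) array (or single point) of mm coordinates."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies *other* first, then *self*."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    # --- diagnostics -----------------------------------------------------
    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees.

        Uses atan2 of the skew part against the trace, which stays accurate
        for rotations near the identity (arccos of the trace does not).
        """
        R = self.rotation
        axis = 0.5 * np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        s = np.linalg.norm(axis)
        c = (np.trace(R) - 1.0) / 2.0
        return float(np.rad2deg(np.arctan2(s, c)))

    def translation_norm(self) -> float:
        return float(np.linalg.norm(self.translation))

    # --- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rotation": [float(x) for x in self.rotation.ravel()],  # row-major
            "translation": [float(x) for x in self.translation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            np.asarray(d["rotation"], dtype=float).reshape(3, 3),
            np.asarray(d["translation"], dtype=float),
        )
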