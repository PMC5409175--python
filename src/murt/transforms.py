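"""Rigid transforms and dense deformation fields in world millimetres.

Conventions
-----------
* World frame: RAS-like, millimetres, fixed per session.
* A :class:`RigidTransform` maps *moving*-world points to *fixed*-world
  points: ``y = R @ x + t``.
* A :class:`DeformationField` is stored on a target (fixed) grid as a
  pull-back map: a point ``x`` on the fixed grid samples the moving image
  at ``x + u(x)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

_ORTHO_TOL = 1e-9


class TransformError(ValueError):
    """Invalid transform parameters (non-orthonormal rotation, bad shapes)."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map ``y = rotation @ x + translation`` in world mm."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > 1e-6:
            raise TransformError(f"rotation is not orthonormal (|R'R - I| = {err:.3g})")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise TransformError("rotation must be proper (det = +1)")
        # re-orthonormalize to keep long composition chains well conditioned
        u, _, vt = np.linalg.svd(R)
        R = u @ vt
        if np.linalg.det(R) < 0:
            u[:, -1] *= -1
            R = u @ vt
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors -------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_euler(angles_deg, translation=(0.0, 0.0, 0.0), order: str = "xyz") -> "RigidTransform":
        """Rigid transform from extrinsic Euler angles in degrees."""
        R = np.eye(3)
        for axis, ang in zip(order, np.atleast_1d(angles_deg)):
            R = _axis_rotation(axis, np.deg2rad(ang)) @ R
        return RigidTransform(R, np.asarray(translation, dtype=float))

    @staticmethod
    def from_matrix(matrix: np.ndarray) -> "RigidTransform":
        m = np.asarray(matrix, dtype=float)
        return RigidTransform(m[:3, :3], m[:3, 3])

    # -- algebra ------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map N×3 (or length-3) world points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply *other* first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    # -- diagnostics ---------------------------------------------------
    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))

    def translation_norm(self) -> float:
        return float(np.linalg.norm(self.translation))

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}

    @staticmethod
    def from_dict(d: dict) -> "RigidTransform":
        return RigidTransform(np.asarray(d["rotation"]), np.asarray(d["translation"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @staticmethod
    def load(path) -> "RigidTransform":
        with open(path) as fh:
            return RigidTransform.from_dict(json.load(fh))


def _axis_rotation(axis: str, theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    raise ValueError(f"unknown axis {axis!r}")


@dataclass
class DeformationField:
    """Dense displacement field (mm) on a stated grid.

    ``displacements`` has shape ``(nx, ny, nz, 3)``; component ``u(x)`` is a
    world-mm vector.  The field acts as a pull-back: resampling a moving
    image onto this grid samples it at ``x + u(x)``.
    """

    displacements: np.ndarray
    grid_affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        u = np.asarray(self.displacements, dtype=float)
        if u.ndim != 4 or u.shape[-1] != 3:
            raise TransformError(f"displacements must be (nx,ny,nz,3), got {u.shape}")
        if not np.all(np.isfinite(u)):
            raise TransformError("displacement field contains non-finite values")
        self.displacements = u
        self.grid_affine = np.asarray(self.grid_affine, dtype=float).reshape(4, 4)

    @property
    def shape(self):
        return self.displacements.shape[:3]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.displacements, axis=-1)

    def at(self, points_world: np.ndarray, order: int = 1) -> np.ndarray:
        """Interpolate the displacement at arbitrary world points (mm)."""
        p = np.atleast_2d(np.asarray(points_world, dtype=float))
        inv = np.linalg.inv(self.grid_affine)
        idx = p @ inv[:3, :3].T + inv[:3, 3]
        coords = idx.T
        out = np.stack(
            [map_coordinates(self.displacements[..., c], coords, order=order,
                             mode="nearest") for c in range(3)], axis=-1)
        return out if np.asarray(points_world).ndim > 1 else out[0]

    def apply(self, points_world: np.ndarray) -> np.ndarray:
        """Map fixed-world points to moving-world points ``x + u(x)``."""
        return np.asarray(points_world, dtype=float) + self.at(points_world)

    def inverse(self, n_iter: int = 30, tol: float = 1e-3) -> "DeformationField":
        """Numerical inverse by fixed-point iteration on the same grid.

        Finds ``v`` with ``v(x) ≈ -u(x + v(x))``, accurate for smooth,
        moderate-amplitude fields.
        """
        shape = self.shape
        ii = np.indices(shape).reshape(3, -1).T.astype(float)
        x = ii @ self.grid_affine[:3, :3].T + self.grid_affine[:3, 3]
        v = np.zeros_like(x)
        for _ in range(n_iter):
            v_new = -self.at(x + v)
            if np.abs(v_new - v).max() < tol:
                v = v_new
                break
            v = v_new
        return DeformationField(v.reshape(*shape, 3), self.grid_affine.copy())
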