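"""Intrinsic/extrinsic motion and MR geometric-distortion models.

Each operation returns the warped object together with the exact
displacement field (or rigid transform) that was applied, so registration
accuracy can be scored against ground truth.

Displacement fields follow the toolkit's pull-back convention: the warped
image is ``out(x) = in(x + u(x))``.  A zero motion spec returns the input
bit-identical, with an identity truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ..image import Grid, ImageVolume, Modality, resample
from ..structures import StructureSet
from ..transforms import DeformationField, RigidTransform


@dataclass(frozen=True)
class MotionSpec:
    droop_mm: float = 0.0                # gravity sag, peak at the free surface
    bladder_growth_fraction: float = 0.0  # fractional volume increase
    gi_amplitude_mm: float = 0.0         # local peristaltic warp, peak mm
    jitter_rotation_deg: float = 0.0     # extrinsic transfer pose
    jitter_translation_mm: float = 0.0
    distortion_amplitude_mm: float = 0.0  # MR polynomial warp, peak mm
    seed: int = 0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if f.name != "seed" and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    def is_zero(self, kind: str) -> bool:
        if kind == "intrinsic":
            return (self.droop_mm == 0 and self.bladder_growth_fraction == 0
                    and self.gi_amplitude_mm == 0)
        if kind == "extrinsic":
            return self.jitter_rotation_deg == 0 and self.jitter_translation_mm == 0
        return self.distortion_amplitude_mm == 0


def apply_motion(obj, motion: MotionSpec, kind: str, anatomy: StructureSet | None = None):
    """Apply a motion model to an :class:`ImageVolume` or :class:`StructureSet`.

    ``kind`` is ``'intrinsic'`` (droop + bladder filling + GI warp),
    ``'extrinsic'`` (one rigid transfer-pose perturbation) or
    ``'mr_distortion'`` (smooth low-order polynomial warp).  Intrinsic
    motion needs ``anatomy`` (or a StructureSet input) to locate body,
    bladder and bowel.  Returns ``(warped, truth)`` where truth is a
    :class:`DeformationField` or, for extrinsic, a :class:`RigidTransform`.
    """
    if kind not in ("intrinsic", "extrinsic", "mr_distortion"):
        raise ValueError(f"unknown motion kind {kind!r}")
    grid = _grid_of(obj)
    if motion.is_zero(kind):
        truth = (RigidTransform.identity() if kind == "extrinsic" else
                 DeformationField(np.zeros((*grid.shape, 3)), grid.affine))
        return obj, truth

    rng = np.random.default_rng(motion.seed)
    if kind == "extrinsic":
        T = _random_rigid(rng, motion.jitter_rotation_deg,
                          motion.jitter_translation_mm, _centre(grid))
        return _apply_rigid(obj, T, grid), T

    if kind == "intrinsic":
        ana = anatomy if anatomy is not None else obj
        if not isinstance(ana, StructureSet):
            raise ValueError("intrinsic motion requires a StructureSet anatomy")
        u = _intrinsic_field(grid, motion, ana, rng)
    else:
        u = _polynomial_field(grid, motion.distortion_amplitude_mm, rng)
    fld = DeformationField(u, grid.affine)
    return _apply_field(obj, fld, grid), fld


# ---------------------------------------------------------------------------

def _grid_of(obj) -> Grid:
    if isinstance(obj, ImageVolume):
        return Grid.of(obj)
    if isinstance(obj, StructureSet):
        return Grid(obj.affine.copy(), tuple(obj.shape))
    raise TypeError(f"cannot apply motion to {type(obj)!r}")


def _centre(grid: Grid) -> np.ndarray:
    c = (np.asarray(grid.shape, float) - 1) / 2.0
    return c @ grid.affine[:3, :3].T + grid.affine[:3, 3]


def _world(grid: Grid) -> np.ndarray:
    ii = np.indices(grid.shape).astype(float)
    return np.moveaxis(ii, 0, -1) @ grid.affine[:3, :3].T + grid.affine[:3, 3]


def _random_rigid(rng, rot_deg, trans_mm, centre) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rot_deg) * rng.uniform(0.5, 1.0)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    tdir = rng.normal(size=3)
    tdir /= np.linalg.norm(tdir)
    t = tdir * trans_mm * rng.uniform(0.5, 1.0)
    # rotate about the volume centre, then translate
    return RigidTransform(R, centre - R @ centre + t)


def _intrinsic_field(grid: Grid, motion: MotionSpec, anatomy: StructureSet, rng):
    w = _world(grid)
    u = np.zeros((*grid.shape, 3))

    body = anatomy.mask("body") if anatomy.has("body") else None
    if motion.droop_mm > 0:
        # sag toward the cradle: zero at the contact line (lowest body z),
        # peak droop_mm at the free (upper) surface
        if body is not None and body.any():
            zvals = w[..., 2][body | (anatomy.labels > 0)]
            z_lo, z_hi = float(zvals.min()), float(zvals.max())
        else:
            z_lo, z_hi = float(w[..., 2].min()), float(w[..., 2].max())
        frac = np.clip((w[..., 2] - z_lo) / max(z_hi - z_lo, 1e-9), 0.0, 1.0)
        u[..., 2] += motion.droop_mm * frac   # pull-back: anatomy moves down

    if motion.bladder_growth_fraction > 0 and anatomy.has("bladder"):
        c = anatomy.centroid_world("bladder")
        R = (3.0 * anatomy.volume_mm3("bladder") / (4 * np.pi)) ** (1 / 3)
        delta = R * ((1 + motion.bladder_growth_fraction) ** (1 / 3) - 1.0)
        d = w - c
        r = np.linalg.norm(d, axis=-1)
        rhat = d / np.maximum(r, 1e-9)[..., None]
        amp = delta * np.exp(-(((r - R) / (0.6 * R)) ** 2))
        u += -amp[..., None] * rhat           # inflate: sample nearer the centre

    if motion.gi_amplitude_mm > 0 and anatomy.has("bowel"):
        spacing = float(np.linalg.norm(grid.affine[:3, :3], axis=0).mean())
        sig = 3.0 / spacing                   # ~3 mm correlation length
        noise = rng.normal(size=(*grid.shape, 3))
        for c3 in range(3):
            noise[..., c3] = gaussian_filter(noise[..., c3], sig)
        window = gaussian_filter(anatomy.mask("bowel").astype(float), sig)
        window /= max(window.max(), 1e-9)
        noise *= window[..., None]
        peak = np.linalg.norm(noise, axis=-1).max()
        u += noise * (motion.gi_amplitude_mm / max(peak, 1e-12))
    return u


def _polynomial_field(grid: Grid, amplitude: float, rng):
    """Smooth degree-2 polynomial warp over normalized FOV coordinates,
    scaled to the requested peak amplitude.  No constant term: bulk shifts
    belong to the pose, not to geometric distortion."""
    w = _world(grid)
    lo = w.reshape(-1, 3).min(axis=0)
    hi = w.reshape(-1, 3).max(axis=0)
    q = 2.0 * (w - lo) / np.maximum(hi - lo, 1e-9) - 1.0   # in [-1, 1]
    x, y, z = q[..., 0], q[..., 1], q[..., 2]
    basis = [x, y, z, x * y, y * z, x * z, x * x, y * y, z * z]
    u = np.zeros((*grid.shape, 3))
    coeffs = rng.normal(size=(3, len(basis)))
    for c3 in range(3):
        for cf, b in zip(coeffs[c3], basis):
            u[..., c3] += cf * b
    peak = np.linalg.norm(u, axis=-1).max()
    return u * (amplitude / max(peak, 1e-12))


def _apply_rigid(obj, T: RigidTransform, grid: Grid):
    if isinstance(obj, ImageVolume):
        return resample(obj, T, grid)
    warped = resample(obj.as_volume(), T, grid, interpolation="nearest")
    return StructureSet(warped.voxels, grid.affine, obj.names, dict(obj.meta))


def _apply_field(obj, fld: DeformationField, grid: Grid):
    if isinstance(obj, ImageVolume):
        return resample(obj, fld, grid)
    warped = resample(obj.as_volume(), fld, grid, interpolation="nearest")
    return StructureSet(warped.voxels, grid.affine, obj.names, dict(obj.meta))
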