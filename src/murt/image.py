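"""Volume data model, NIfTI/MetaImage I/O, resampling and difference images.

All grids carry a 4x4 voxel-index -> world-mm affine (0-based indices,
RAS-like world frame).  Registration and dose computation always operate
in world mm, so CT and MR grids never need matching spacings.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .transforms import DeformationField, RigidTransform


class Modality(enum.Enum):
    CT = "CT"
    MR_BSSFP = "MR_bSSFP"
    MR_CPMG = "MR_CPMG"
    MR_CEFAST = "MR_CEFAST"
    DOSE = "DOSE"
    LABEL = "LABEL"


class FormatError(ValueError):
    """Unreadable or inconsistent volume file."""


class GridMismatchError(ValueError):
    """Operation requires volumes sharing a grid."""


@dataclass
class ImageVolume:
    """3D scalar grid + voxel-to-world affine + modality tag."""

    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    modality: Modality = Modality.CT
    frame: str = "world"

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise FormatError(f"voxels must be 3D, got shape {v.shape}")
        A = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if abs(np.linalg.det(A[:3, :3])) < 1e-12:
            raise FormatError("affine is singular")
        if np.any(np.linalg.norm(A[:3, :3], axis=0) <= 0):
            raise FormatError("voxel spacings must be strictly positive")
        if isinstance(self.modality, str):
            self.modality = Modality(self.modality)
        if self.modality is Modality.DOSE and np.any(v < -1e-9):
            raise FormatError("DOSE volumes must be non-negative everywhere")
        self.voxels = v
        self.affine = A

    # -- geometry ------------------------------------------------------
    @property
    def shape(self):
        return self.voxels.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacings in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def origin(self) -> np.ndarray:
        return self.affine[:3, 3].copy()

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        p = np.asarray(idx, dtype=float)
        return p @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        p = np.asarray(pts, dtype=float)
        return p @ inv[:3, :3].T + inv[:3, 3]

    def world_grid(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*shape, 3)``."""
        ii = np.indices(self.shape).astype(float)
        idx = np.moveaxis(ii, 0, -1)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def centre_world(self) -> np.ndarray:
        return self.index_to_world((np.asarray(self.shape, float) - 1) / 2.0)

    def same_grid(self, other: "ImageVolume", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=tol)

    def with_voxels(self, voxels: np.ndarray, modality: Modality | None = None) -> "ImageVolume":
        return replace(self, voxels=voxels,
                       modality=self.modality if modality is None else modality)

    def sample_world(self, pts: np.ndarray, order: int = 1, fill: float = 0.0) -> np.ndarray:
        """Interpolate voxel values at arbitrary world points."""
        idx = self.world_to_index(np.atleast_2d(pts))
        return map_coordinates(self.voxels.astype(float), idx.T, order=order,
                               mode="constant", cval=fill)


@dataclass
class Grid:
    """A target sampling lattice: affine + shape, without data."""

    affine: np.ndarray
    shape: tuple

    @staticmethod
    def of(volume: ImageVolume) -> "Grid":
        return Grid(volume.affine.copy(), tuple(volume.shape))

    @staticmethod
    def from_extent(lo, hi, spacing: float) -> "Grid":
        """Axis-aligned grid covering world box [lo, hi] at isotropic spacing."""
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        n = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
        A = np.eye(4)
        A[:3, :3] *= spacing
        A[:3, 3] = lo
        return Grid(A, tuple(n))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_NIFTI_EXT = (".nii", ".nii.gz")


def write_volume(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
    path = os.fspath(path)
    if path.endswith(_NIFTI_EXT):
        img = nib.Nifti1Image(np.asanyarray(volume.voxels), volume.affine)
        img.header.set_qform(volume.affine, code=1)
        img.header.set_sform(volume.affine, code=1)
        img.header["descrip"] = volume.modality.value.encode()[:79]
        nib.save(img, path)
    elif path.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        sim = _to_sitk(volume)
        sitk.WriteImage(sim, path)
    else:
        raise FormatError(f"unsupported volume format for {path!r}")


def read_volume(path: str | os.PathLike, format: str | None = None,
                modality: Modality | str | None = None) -> ImageVolume:
    """Read a NIfTI or MetaImage volume into an :class:`ImageVolume`.

    The returned affine reproduces the file's voxel-to-world map.  The
    modality is taken from the NIfTI ``descrip`` field when it matches a
    known tag, unless overridden.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    fmt = format or ("nifti" if path.endswith(_NIFTI_EXT) else
                     "metaimage" if path.endswith((".mha", ".mhd")) else None)
    if fmt == "nifti":
        try:
            img = nib.load(path)
            voxels = np.asanyarray(img.dataobj)
            affine = img.affine
        except Exception as exc:  # pragma: no cover - nibabel error text varies
            raise FormatError(f"cannot parse {path!r} as NIfTI (header): {exc}") from exc
        if voxels.ndim == 4 and voxels.shape[-1] == 1:
            voxels = voxels[..., 0]
        mod = modality
        if mod is None:
            descrip = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="ignore")
            try:
                mod = Modality(descrip)
            except ValueError:
                mod = Modality.CT
        return ImageVolume(voxels, affine, Modality(mod) if isinstance(mod, str) else mod)
    if fmt == "metaimage":
        import SimpleITK as sitk

        try:
            sim = sitk.ReadImage(path)
        except Exception as exc:
            raise FormatError(f"cannot parse {path!r} as MetaImage: {exc}") from exc
        return _from_sitk(sim, Modality(modality) if modality else Modality.CT)
    raise FormatError(f"unknown volume format for {path!r}")


def _to_sitk(volume: ImageVolume):
    """Convert to a SimpleITK image, preserving this package's world frame."""
    import SimpleITK as sitk

    # sitk indexes (z,y,x); keep world frame identical by passing direction
    sim = sitk.GetImageFromArray(np.ascontiguousarray(
        np.transpose(volume.voxels, (2, 1, 0)).astype(np.float64)))
    sp = volume.spacing
    direction = volume.affine[:3, :3] / sp[np.newaxis, :]
    sim.SetSpacing(tuple(float(s) for s in sp))
    sim.SetOrigin(tuple(float(o) for o in volume.origin))
    sim.SetDirection(tuple(direction.flatten()))
    return sim


def _from_sitk(sim, modality: Modality = Modality.CT) -> ImageVolume:
    import SimpleITK as sitk

    voxels = np.transpose(sitk.GetArrayFromImage(sim), (2, 1, 0))
    sp = np.asarray(sim.GetSpacing())
    direction = np.asarray(sim.GetDirection()).reshape(3, 3)
    A = np.eye(4)
    A[:3, :3] = direction * sp[np.newaxis, :]
    A[:3, 3] = np.asarray(sim.GetOrigin())
    return ImageVolume(voxels, A, modality)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(moving: ImageVolume,
             transform: RigidTransform | DeformationField | None = None,
             target: ImageVolume | Grid | None = None,
             interpolation: str | None = None,
             fill: float = 0.0) -> ImageVolume:
    """Resample ``moving`` onto ``target``'s grid under ``transform``.

    A :class:`RigidTransform` is the physical map from moving-world to
    target-world; sampling uses its inverse.  A :class:`DeformationField`
    must live on a grid compatible with ``target`` and acts as a pull-back
    (target point ``x`` samples the moving image at ``x + u(x)``).

    ``interpolation`` is ``'linear'`` or ``'nearest'``; LABEL volumes
    default to nearest, everything else to linear.  Out-of-field voxels
    take ``fill`` (default 0, i.e. air/background).
    """
    if target is None:
        target = Grid.of(moving)
    elif isinstance(target, ImageVolume):
        target = Grid.of(target)
    if interpolation is None:
        interpolation = "nearest" if moving.modality is Modality.LABEL else "linear"
    order = {"linear": 1, "nearest": 0}[interpolation]

    tgt_affine = np.asarray(target.affine, dtype=float)
    ii = np.indices(target.shape).reshape(3, -1).T.astype(float)
    world = ii @ tgt_affine[:3, :3].T + tgt_affine[:3, 3]

    if transform is None:
        src_world = world
    elif isinstance(transform, RigidTransform):
        src_world = transform.inverse().apply(world)
    elif isinstance(transform, DeformationField):
        if transform.shape != tuple(target.shape) or \
                not np.allclose(transform.grid_affine, tgt_affine, atol=1e-6):
            raise GridMismatchError(
                "deformation field grid does not match the target grid "
                f"(field {transform.shape}, target {tuple(target.shape)})")
        src_world = world + transform.displacements.reshape(-1, 3)
    else:
        raise TypeError(f"unsupported transform type {type(transform)!r}")

    idx = moving.world_to_index(src_world)
    vox = map_coordinates(moving.voxels.astype(float), idx.T, order=order,
                          mode="constant", cval=fill).reshape(target.shape)
    if moving.modality is Modality.LABEL:
        vox = np.rint(vox).astype(moving.voxels.dtype)
    if moving.modality is Modality.DOSE:
        vox = np.maximum(vox, 0.0)
    return ImageVolume(vox, tgt_affine.copy(), moving.modality, moving.frame)


# ---------------------------------------------------------------------------
# Difference images
# ---------------------------------------------------------------------------

def difference_image(a: ImageVolume, b: ImageVolume, structures=None):
    """Signed voxelwise ``a - b`` on a shared grid.

    With a structure set, also returns per-region mean absolute difference
    expressed as a percentage of ``a``'s regional mean (the first image is
    the denominator).
    """
    if not a.same_grid(b):
        raise GridMismatchError("difference_image requires volumes on the same grid")
    if a.modality is not b.modality:
        raise GridMismatchError("difference_image requires matching modalities")
    diff = ImageVolume(a.voxels.astype(float) - b.voxels.astype(float),
                       a.affine.copy(), a.modality, a.frame)
    if structures is None:
        return diff
    stats = {}
    for name in structures.names.values():
        m = structures.mask(name)
        if not m.any():
            continue
        denom = float(np.abs(a.voxels[m]).mean())
        mad = float(np.abs(diff.voxels[m]).mean())
        stats[name] = 100.0 * mad / denom if denom > 0 else np.inf
    return diff, stats
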