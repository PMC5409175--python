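"""Region-growing segmentation and surface point extraction.

The gel workflow segments the gel (not the glass vial) from CT by growing
an intensity window from a seed, then converts the mask boundary into a
point cloud that drives surface ICP.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes

from ..image import ImageVolume
from ..structures import StructureSet


class SeedError(ValueError):
    """Seed point intensity falls outside the requested window."""


class EmptyMaskError(ValueError):
    """Operation requires a nonempty mask."""


def segment_region_growing(volume: ImageVolume, seed_world, window,
                           name: str = "region") -> StructureSet:
    """26-connected component of window-satisfying voxels containing the seed.

    ``window`` is an inclusive intensity interval (lo, hi).  For gel CT,
    choose a window that includes the gel but excludes the glass wall so
    only the gel is grown.
    """
    lo, hi = window
    seed_idx = np.rint(volume.world_to_index(np.asarray(seed_world, float))).astype(int)
    if np.any(seed_idx < 0) or np.any(seed_idx >= np.asarray(volume.shape)):
        raise SeedError(f"seed {seed_world} lies outside the volume")
    val = float(volume.voxels[tuple(seed_idx)])
    if not (lo <= val <= hi):
        raise SeedError(f"seed intensity {val:.1f} outside window [{lo}, {hi}]")
    candidate = (volume.voxels >= lo) & (volume.voxels <= hi)
    labels, _ = ndimage.label(candidate, structure=np.ones((3, 3, 3), dtype=int))
    comp = labels == labels[tuple(seed_idx)]
    return StructureSet(comp.astype(np.int16), volume.affine.copy(), {1: name},
                        meta={"window": [float(lo), float(hi)],
                              "seed_world": list(map(float, np.asarray(seed_world, float)))})


def mask_to_surface_points(mask, affine=None, spacing: float = 0.5,
                           intensity: np.ndarray | None = None,
                           levels=None,
                           max_points: int | None = None,
                           rng=None) -> np.ndarray:
    """Convert a mask boundary to an approximately uniform N x 3 point cloud.

    The boundary is triangulated and vertices are pooled on a cubic lattice
    of pitch ``spacing`` mm (one averaged point per occupied cell), giving
    near-uniform density of about ``area / spacing**2`` points.  Accepts a
    boolean array + affine or a single-structure :class:`StructureSet`.

    By default the triangulation runs on the (smoothed) binary mask, which
    quantizes flat boundaries to the grid phase.  When the source
    ``intensity`` image and the segmentation window ``levels = (lo, hi)``
    are supplied, the surface is instead taken at the intensity iso-levels
    themselves (restricted to the mask's neighbourhood), which localises
    boundaries with subvoxel accuracy independent of the grid — essential
    when clouds from grids of different pitch are registered.  Pass
    ``hi=None`` when the structure is the brightest thing in the image.
    """
    if isinstance(mask, StructureSet):
        affine = mask.affine
        if levels is None and "window" in mask.meta:
            levels = mask.meta["window"]
        mask = mask.labels > 0
    mask = np.asarray(mask)
    if mask.dtype != bool:
        mask = mask > 0
    if not mask.any():
        raise EmptyMaskError("cannot extract surface points from an empty mask")
    A = np.eye(4) if affine is None else np.asarray(affine, dtype=float)

    if mask.sum() == 1 or min(mask.shape) < 2:
        # single voxel (or degenerate grid): return its face centres
        idx = np.argwhere(mask)[0].astype(float)
        sp = np.linalg.norm(A[:3, :3], axis=0)
        faces = []
        for ax in range(3):
            for s in (-0.5, 0.5):
                f = idx.copy()
                f[ax] += s
                faces.append(f)
        return np.asarray(faces) @ A[:3, :3].T + A[:3, 3]

    if intensity is not None and levels is not None:
        verts = _isolevel_vertices(np.asarray(intensity, dtype=float), mask, levels)
    else:
        padded = np.pad(mask.astype(np.float32), 2)
        padded = ndimage.gaussian_filter(padded, 1.0)
        verts, *_ = marching_cubes(padded, level=0.5)
        verts -= 2.0
    pts = verts @ A[:3, :3].T + A[:3, 3]

    if len(pts) == 0:
        raise EmptyMaskError("no boundary vertices found")
    # uniform pooling: average all vertices falling in each spacing-cell
    cells = np.floor(pts / spacing).astype(np.int64)
    _, inv = np.unique(cells, axis=0, return_inverse=True)
    n = inv.max() + 1
    sums = np.zeros((n, 3))
    counts = np.bincount(inv, minlength=n).astype(float)
    for c in range(3):
        sums[:, c] = np.bincount(inv, weights=pts[:, c], minlength=n)
    pooled = sums / counts[:, None]
    if max_points is not None and len(pooled) > max_points:
        rng = np.random.default_rng(0) if rng is None else rng
        pooled = pooled[rng.choice(len(pooled), max_points, replace=False)]
    return pooled


def boundary_shell(mask: np.ndarray, thickness_vox: int = 3) -> np.ndarray:
    """Shell of +/- ``thickness_vox`` voxels around a mask's boundary.

    Used as a registration ROI: the subject outline is the one structure
    reliably visible in every modality, so restricting cross-modality
    evidence to this shell avoids bias from one-sided interior edges.
    """
    mask = np.asarray(mask, bool)
    return (ndimage.binary_dilation(mask, iterations=thickness_vox)
            & ~ndimage.binary_erosion(mask, iterations=thickness_vox))


def _isolevel_vertices(intensity: np.ndarray, mask: np.ndarray, levels) -> np.ndarray:
    """Triangulation vertices of the mask boundary taken at the intensity
    window's own iso-levels (lo on the dark side, hi on the bright side),
    restricted to the mask's immediate neighbourhood."""
    lo, hi = levels
    img = ndimage.gaussian_filter(intensity, 0.5)
    near = ndimage.gaussian_filter(mask.astype(np.float32), 1.0)
    verts_all = []
    use_levels = [lv for lv in (lo, hi) if lv is not None
                  and img.min() < lv < img.max()]
    for lv in use_levels:
        v, *_ = marching_cubes(img, level=float(lv))
        keep = ndimage.map_coordinates(near, v.T, order=1) > 0.2
        if keep.any():
            verts_all.append(v[keep])
    if not verts_all:
        raise EmptyMaskError("no iso-level boundary found near the mask")
    return np.vstack(verts_all)
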