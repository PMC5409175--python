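"""Digital rotationally-asymmetric polymer-gel vial phantoms.

A radiosensitive gel sets inside a glass vial that was held at an angle, so
the meniscus is a tilted plane and the gel volume has no rotational symmetry
about the vial axis.  That asymmetry is what makes marker-free surface
registration between MR and CT well-posed.  CT shows both the glass wall and
the gel; MR shows the gel only.

World frame: vial axis along +z (vertical), vial bottom inner surface at
z = 0, axis through x = y = 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ..image import Grid, ImageVolume, Modality
from ..structures import StructureSet

# CT scale convention used throughout the toolkit: air = 0, water-equivalent
# (gel) = 1000; the dose engine's two-point attenuation calibration relies
# on exactly this pair.
CT_AIR = 0.0
CT_WATER = 1000.0
CT_GLASS = 2400.0
MR_GEL = 1000.0


@dataclass(frozen=True)
class GelPhantomSpec:
    """Geometry, contrast and noise of a virtual BANG-type gel vial."""

    inner_diameter_mm: float = 25.0
    wall_thickness_mm: float = 1.5
    gel_height_mm: float = 15.0          # height of the gel column on the axis
    vial_height_mm: float = 20.0
    meniscus_tilt_deg: float = 15.0      # nonzero => rotationally asymmetric
    ct_spacing_mm: float = 0.16
    mr_spacing_mm: float = 0.27
    ct_noise_sigma: float = 20.0         # Gaussian, CT units
    mr_snr: float = 20.0                 # Rician, relative to gel signal
    margin_mm: float = 2.5
    seed: int = 0

    def replace(self, **kw) -> "GelPhantomSpec":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class GelResponse:
    """Saturating-exponential dose response of the virtual gel.

    Signal change for absorbed dose D is ``s_max * (1 - exp(-k * D))``; the
    polymerised gel darkens, so the change is subtracted from the pristine
    signal.  ``visible_dose_gy`` documents the dose at which the change
    clears ~3 noise SD at default noise.
    """

    s_max: float = 600.0
    k_per_gy: float = 0.35
    visible_dose_gy: float = 1.0

    def signal_change(self, dose_gy: np.ndarray) -> np.ndarray:
        d = np.asarray(dose_gy, dtype=float)
        if np.any(d < -1e-9):
            raise ValueError("negative dose passed to gel response")
        return self.s_max * (1.0 - np.exp(-self.k_per_gy * np.maximum(d, 0.0)))

    def dose_from_change(self, change: np.ndarray) -> np.ndarray:
        c = np.clip(np.asarray(change, dtype=float), 0.0, self.s_max * (1 - 1e-9))
        return -np.log(1.0 - c / self.s_max) / self.k_per_gy


def _gel_masks(grid: Grid, spec: GelPhantomSpec):
    """Analytic voxelization of gel and vial on a grid. Returns (gel, vial)."""
    A = grid.affine
    ii = np.indices(grid.shape).astype(float)
    idx = np.moveaxis(ii, 0, -1)
    w = idx @ A[:3, :3].T + A[:3, 3]
    x, y, z = w[..., 0], w[..., 1], w[..., 2]
    r = np.hypot(x, y)
    ri = spec.inner_diameter_mm / 2.0
    ro = ri + spec.wall_thickness_mm
    slope = np.tan(np.deg2rad(spec.meniscus_tilt_deg))
    surface = spec.gel_height_mm + slope * x
    gel = (r <= ri) & (z >= 0.0) & (z <= surface)
    wall_side = (r > ri) & (r <= ro) & (z >= -spec.wall_thickness_mm) & (z <= spec.vial_height_mm)
    wall_bottom = (r <= ri) & (z < 0.0) & (z >= -spec.wall_thickness_mm)
    return gel, wall_side | wall_bottom


def make_gel_phantom(spec: GelPhantomSpec | None = None):
    """Render a gel vial in CT-like and MR-like contrast.

    Returns ``(ct, mr, truth)``.  The CT rendering shows gel and glass wall
    at distinct intensities; the MR rendering shows the gel only.  ``truth``
    holds {gel, vial} labels on the CT grid.  Identical seeds give
    bit-identical volumes.
    """
    spec = spec or GelPhantomSpec()
    rng = np.random.default_rng(spec.seed)
    ro = spec.inner_diameter_mm / 2.0 + spec.wall_thickness_mm
    m = spec.margin_mm
    top = spec.gel_height_mm + ro * abs(np.tan(np.deg2rad(spec.meniscus_tilt_deg))) + m
    lo = np.array([-ro - m, -ro - m, -spec.wall_thickness_mm - m])
    hi = np.array([ro + m, ro + m, max(top, spec.vial_height_mm + m)])

    ct_grid = Grid.from_extent(lo, hi, spec.ct_spacing_mm)
    mr_grid = Grid.from_extent(lo, hi, spec.mr_spacing_mm)

    gel_ct, vial_ct = _gel_masks(ct_grid, spec)
    ct = np.zeros(ct_grid.shape)
    ct[gel_ct] = CT_WATER
    ct[vial_ct] = CT_GLASS
    ct = gaussian_filter(ct, 0.6)                     # partial-volume blur
    ct += rng.normal(0.0, spec.ct_noise_sigma, ct.shape)

    gel_mr, _ = _gel_masks(mr_grid, spec)
    mr = np.zeros(mr_grid.shape)
    mr[gel_mr] = MR_GEL
    mr = gaussian_filter(mr, 0.6)
    sigma = MR_GEL / spec.mr_snr
    mr = np.hypot(mr + rng.normal(0.0, sigma, mr.shape),
                  rng.normal(0.0, sigma, mr.shape))   # Rician magnitude noise

    meta = {"spec": dataclasses.asdict(spec)}
    if spec.meniscus_tilt_deg == 0.0:
        meta["warning"] = ("meniscus tilt is zero: the gel is rotationally "
                           "symmetric and surface registration about the vial "
                           "axis is degenerate")
    truth = StructureSet.from_masks({"gel": gel_ct, "vial": vial_ct & ~gel_ct},
                                    ct_grid.affine, meta)
    return (ImageVolume(ct, ct_grid.affine, Modality.CT),
            ImageVolume(mr, mr_grid.affine, Modality.MR_CEFAST),
            truth)


def rotational_asymmetry_rms(mask: np.ndarray, affine: np.ndarray,
                             angle_deg: float = 90.0,
                             axis_point=(0.0, 0.0, 0.0)) -> float:
    """RMS nearest-surface distance (mm) between a mask's surface and the
    same surface rotated about the vial (z) axis.

    Large values mean the shape has no rotational symmetry; ~0 means the
    rotation maps the surface onto itself.
    """
    from scipy.spatial import cKDTree
    from skimage.measure import marching_cubes

    verts, *_ = marching_cubes(mask.astype(np.float32), level=0.5)
    A = np.asarray(affine, dtype=float)
    pts = verts @ A[:3, :3].T + A[:3, 3]
    th = np.deg2rad(angle_deg)
    Rz = np.array([[np.cos(th), -np.sin(th), 0],
                   [np.sin(th), np.cos(th), 0],
                   [0, 0, 1.0]])
    c = np.asarray(axis_point, dtype=float)
    rotated = (pts - c) @ Rz.T + c
    d, _ = cKDTree(pts).query(rotated, workers=-1)
    return float(np.sqrt(np.mean(d ** 2)))
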