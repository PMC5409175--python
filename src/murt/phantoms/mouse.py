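"""Labelled abdominal mouse phantom with modality-specific contrast.

The phantom is a supine mouse abdomen built from analytic ellipsoids: body
envelope, pancreatic tumour in the upper-right abdomen, kidneys with small
(1.5-3 mm) adrenal glands cranial to them, liver, spleen, stomach, a bowel
compartment and a bladder.  Three renderings are produced:

* CT: flat soft-tissue contrast (organ values span <= 30 units around
  water) with Gaussian noise — tumour and adrenals are not visible
  (contrast-to-noise ratio < 1), as for a low-kVp cone-beam CT.
* bSSFP MR: bright-fluid contrast with Rician noise — adrenals and tumour
  clearly visible (CNR >= 5).
* CPMG MR: T2-weighted contrast giving the highest tumour-to-tissue CNR.

World frame (mm): x = left(-)/right(+), y = caudal(-)/cranial(+),
z = dorsal(-)/ventral(+); the animal lies supine on a cradle below, so a
0-degree beam travels ventral-to-dorsal along -z.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from ..image import Grid, ImageVolume, Modality
from ..structures import StructureSet


class PhantomSpecError(ValueError):
    """Invalid phantom geometry (e.g. colliding organs)."""


@dataclass(frozen=True)
class Organ:
    """Axis-aligned ellipsoid: centre and half-axes in world mm."""

    centre: tuple
    radii: tuple

    def contains(self, w: np.ndarray) -> np.ndarray:
        c = np.asarray(self.centre, dtype=float)
        r = np.asarray(self.radii, dtype=float)
        q = (w - c) / r
        return np.einsum("...i,...i->...", q, q) <= 1.0


def _default_organs() -> dict:
    return {
        "body": Organ((0.0, 0.0, 0.0), (14.0, 21.0, 11.0)),
        "tumour": Organ((5.0, 4.0, 2.5), (2.25, 2.25, 2.25)),
        "kidney_L": Organ((-6.0, 2.0, -4.0), (2.5, 4.0, 2.5)),
        "kidney_R": Organ((6.0, 2.0, -4.0), (2.5, 4.0, 2.5)),
        "adrenal_L": Organ((-5.5, 7.6, -4.0), (1.2, 1.2, 1.2)),
        "adrenal_R": Organ((5.5, 7.6, -4.0), (1.2, 1.2, 1.2)),
        "liver": Organ((0.0, 12.5, 1.0), (9.0, 5.0, 5.0)),
        "spleen": Organ((-9.5, 2.0, 0.0), (1.5, 6.0, 2.0)),
        "stomach": Organ((-4.0, 4.0, 4.5), (3.5, 2.8, 2.5)),
        "bowel": Organ((0.0, -8.5, 1.0), (8.0, 6.0, 6.0)),
        "bladder": Organ((0.0, -17.0, 2.5), (2.2, 2.2, 2.2)),
    }


# Per-modality mean intensity per organ.  CT: air 0, water 1000; soft-tissue
# values span <= 30 units so low-contrast targets drown in sigma=20 noise.
DEFAULT_CONTRAST = {
    "CT": {"background": 0.0, "body": 1040.0, "tumour": 1045.0,
           "kidney_L": 1045.0, "kidney_R": 1045.0, "adrenal_L": 1042.0,
           "adrenal_R": 1042.0, "liver": 1055.0, "spleen": 1050.0,
           "stomach": 1025.0, "bowel": 1030.0, "bladder": 1015.0},
    "MR_bSSFP": {"background": 0.0, "body": 400.0, "tumour": 650.0,
                 "kidney_L": 500.0, "kidney_R": 500.0, "adrenal_L": 800.0,
                 "adrenal_R": 800.0, "liver": 350.0, "spleen": 450.0,
                 "stomach": 700.0, "bowel": 550.0, "bladder": 900.0},
    "MR_CPMG": {"background": 0.0, "body": 300.0, "tumour": 900.0,
                "kidney_L": 400.0, "kidney_R": 400.0, "adrenal_L": 550.0,
                "adrenal_R": 550.0, "liver": 250.0, "spleen": 350.0,
                "stomach": 500.0, "bowel": 380.0, "bladder": 850.0},
}


@dataclass(frozen=True)
class MousePhantomSpec:
    organs: dict = field(default_factory=_default_organs)
    contrast: dict = field(default_factory=lambda: {k: dict(v) for k, v in
                                                    DEFAULT_CONTRAST.items()})
    ct_spacing_mm: float = 0.16
    mr_spacing_mm: float = 0.25
    ct_noise_sigma: float = 20.0
    mr_snr: float = 20.0          # relative to the body-tissue signal
    margin_mm: float = 2.0
    seed: int = 0

    def replace(self, **kw) -> "MousePhantomSpec":
        return dataclasses.replace(self, **kw)

    def fov(self):
        body = self.organs["body"]
        c = np.asarray(body.centre)
        r = np.asarray(body.radii)
        return c - r - self.margin_mm, c + r + self.margin_mm


def kpc_dvh_spec(tumour_diameter_mm: float = 7.0, **kw) -> MousePhantomSpec:
    """Preset for the abdominal plan-comparison study: a larger pancreatic
    tumour in the upper-right abdomen, suited to a 10 mm circular field."""
    organs = _default_organs()
    r = tumour_diameter_mm / 2.0
    organs["tumour"] = Organ((5.0, 4.0, 2.5), (r, r, r))
    return MousePhantomSpec(organs=organs, **kw)


def voxelize_structures(spec: MousePhantomSpec, grid: Grid,
                        check: bool = True) -> StructureSet:
    """Exact analytic voxelization of the spec's organs onto a grid.

    Organs must be pairwise disjoint and inside the body; violations raise
    :class:`PhantomSpecError` naming the colliding pair.  The ``body`` label
    covers body tissue not claimed by any organ.
    """
    A = np.asarray(grid.affine, dtype=float)
    ii = np.indices(grid.shape).astype(float)
    w = np.moveaxis(ii, 0, -1) @ A[:3, :3].T + A[:3, 3]

    masks = {name: org.contains(w) for name, org in spec.organs.items()}
    body = masks.pop("body")
    if check:
        names = list(masks)
        for i, a in enumerate(names):
            if masks[a].any() and not (masks[a] <= body).all():
                raise PhantomSpecError(f"organ {a!r} extends outside the body")
            for b in names[i + 1:]:
                if (masks[a] & masks[b]).any():
                    raise PhantomSpecError(f"organs overlap: ({a!r}, {b!r})")
    ordered = {"body": body}
    for name, m in masks.items():
        ordered[name] = m          # later labels overwrite body where organs sit
    return StructureSet.from_masks(ordered, A, meta={"spec_seed": spec.seed})


def _render(truth: StructureSet, table: dict, blur_vox: float = 0.7) -> np.ndarray:
    img = np.full(truth.shape, float(table.get("background", 0.0)))
    for name in truth.names.values():
        img[truth.mask(name)] = float(table[name])
    return gaussian_filter(img, blur_vox)


def organ_cnr(img: ImageVolume, truth: StructureSet, organ: str,
              noise_sigma: float, reference: str = "body",
              erode_vox: int = 2) -> float:
    """Contrast-to-noise ratio of an organ against surrounding tissue.

    Means are taken on eroded ground-truth masks so partial-volume voxels at
    organ and body boundaries do not bias them; the noise level is the
    generator's (or an independently estimated) sigma.
    """
    from scipy.ndimage import binary_erosion

    def mean_of(name):
        m = truth.mask(name)
        # keep enough voxels for a stable mean on coarse grids
        for it in range(erode_vox, 0, -1):
            er = binary_erosion(m, iterations=it)
            if er.sum() >= 27:
                return float(img.voxels[er].mean())
        return float(img.voxels[m].mean())

    return abs(mean_of(organ) - mean_of(reference)) / float(noise_sigma)


def make_mouse_phantom(spec: MousePhantomSpec | None = None):
    """Generate (ct, mr_bssfp, mr_cpmg, truth).

    ``truth`` is voxelized on the CT grid; use :func:`voxelize_structures`
    for exact masks on any other grid.  Identical seeds give bit-identical
    volumes.
    """
    spec = spec or MousePhantomSpec()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.fov()
    ct_grid = Grid.from_extent(lo, hi, spec.ct_spacing_mm)
    mr_grid = Grid.from_extent(lo, hi, spec.mr_spacing_mm)

    truth_ct = voxelize_structures(spec, ct_grid, check=True)
    truth_mr = voxelize_structures(spec, mr_grid, check=False)

    ct = _render(truth_ct, spec.contrast["CT"])
    if spec.ct_noise_sigma > 0:
        ct = ct + rng.normal(0.0, spec.ct_noise_sigma, ct.shape)

    body_sig = spec.contrast["MR_bSSFP"]["body"]
    vols = []
    for key, modality in (("MR_bSSFP", Modality.MR_BSSFP),
                          ("MR_CPMG", Modality.MR_CPMG)):
        img = _render(truth_mr, spec.contrast[key])
        if spec.mr_snr > 0 and np.isfinite(spec.mr_snr):
            sigma = body_sig / spec.mr_snr
            img = np.hypot(img + rng.normal(0.0, sigma, img.shape),
                           rng.normal(0.0, sigma, img.shape))
        vols.append(ImageVolume(img, mr_grid.affine, modality))

    return (ImageVolume(ct, ct_grid.affine, Modality.CT),
            vols[0], vols[1], truth_ct)
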