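"""Target delineation, comparative plan geometries, DVH analysis and the
end-to-end targeting-accuracy report."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose import BeamSpec, Plan
from .image import GridMismatchError, ImageVolume
from .structures import StructureSet


class EmptyTargetError(ValueError):
    pass


class CoverageWarning(UserWarning):
    """No single collimator covers the target; compose multiple fields."""


class ReadoutError(RuntimeError):
    """No high-dose region found in the gel readout."""


# ---------------------------------------------------------------------------
# Isocentre and collimator selection
# ---------------------------------------------------------------------------

def define_isocentre(target, weights: np.ndarray | None = None,
                     jitter_sigma_mm: float = 0.0, rng=None) -> np.ndarray:
    """(Weighted) centroid of a target mask in world mm, with an optional
    operator-jitter model.

    ``target`` is a single-structure :class:`StructureSet` or a boolean
    mask + implicit identity affine.  ``jitter_sigma_mm`` adds a zero-mean
    isotropic Gaussian offset emulating a human operator prescribing the
    centre by eye; the radial error of that model follows a Maxwell
    distribution with mean ``2 * sigma * sqrt(2/pi)``.
    """
    if isinstance(target, StructureSet):
        mask = target.labels > 0
        affine = target.affine
    else:
        mask = np.asarray(target, bool)
        affine = np.eye(4)
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise EmptyTargetError("target mask is empty")
    if weights is not None:
        wv = np.asarray(weights, float)[mask]
        c = (idx * wv[:, None]).sum(0) / wv.sum()
    else:
        c = idx.mean(0)
    world = c @ affine[:3, :3].T + affine[:3, 3]
    if jitter_sigma_mm > 0:
        rng = np.random.default_rng() if rng is None else rng
        world = world + rng.normal(0.0, jitter_sigma_mm, 3)
    return world


def choose_collimator(target, available=(2.0, 3.0, 5.0, 10.0)) -> float:
    """Smallest available circular field covering the target's maximal
    beam's-eye-view extent (the largest caliper diameter of the mask).

    Emits :class:`CoverageWarning` and returns the largest collimator when
    none covers the target (compose multiple fields manually).
    """
    from .registration.segmentation import mask_to_surface_points

    pts = mask_to_surface_points(target, spacing=0.5)
    try:
        from scipy.spatial import ConvexHull

        hull = pts[ConvexHull(pts).vertices]
    except Exception:
        hull = pts
    diff = hull[:, None, :] - hull[None, :, :]
    extent = float(np.sqrt((diff ** 2).sum(-1)).max())
    for d in sorted(available):
        if d >= extent:
            return float(d)
    warnings.warn(
        f"target extent {extent:.1f} mm exceeds the largest collimator "
        f"({max(available):.0f} mm); use multiple fields with minimal overlap",
        CoverageWarning, stacklevel=2)
    return float(max(available))


# ---------------------------------------------------------------------------
# The four comparative plan geometries
# ---------------------------------------------------------------------------

def make_comparison_plans(isocentre, collimator_mm: float = 10.0,
                          prescription_gy: float = 8.0) -> dict:
    """The four abdominal plan geometries compared in the toolkit's DVH
    study: a 45-degree conical arc, a single vertical beam, a pair of
    conical arcs at 30 and 60 degrees, and two 120-degree gantry arcs
    (equivalent to sweeping the gantry from -120 to +120 degrees)."""
    iso = tuple(np.asarray(isocentre, float))

    def b(**kw):
        return BeamSpec(isocentre=iso, collimator_mm=collimator_mm, **kw)

    return {
        "45deg_arc": Plan([b(kind="conical_arc", gantry_deg=45.0,
                             sweep_deg=(0.0, 360.0))],
                          prescription_gy, name="45deg_arc"),
        "0deg_beam": Plan([b(kind="static", gantry_deg=0.0)],
                          prescription_gy, name="0deg_beam"),
        "30+60deg_arc": Plan([b(kind="conical_arc", gantry_deg=30.0,
                                sweep_deg=(0.0, 360.0)),
                              b(kind="conical_arc", gantry_deg=60.0,
                                sweep_deg=(0.0, 360.0))],
                             prescription_gy, name="30+60deg_arc"),
        "2x120deg_arcs": Plan([b(kind="gantry_arc", sweep_deg=(0.0, 120.0)),
                               b(kind="gantry_arc", sweep_deg=(0.0, -120.0))],
                              prescription_gy, name="2x120deg_arcs"),
    }


# ---------------------------------------------------------------------------
# Dose-volume histograms
# ---------------------------------------------------------------------------

@dataclass
class DVHCurve:
    """Cumulative DVH: % of structure volume receiving >= each dose edge."""

    structure: str
    edges_gy: np.ndarray
    cum_volume_pct: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.cum_volume_pct, float)
        if v.size and (v[0] < 100.0 - 1e-9 or np.any(np.diff(v) > 1e-9)):
            raise ValueError("cumulative DVH must start at 100% and be non-increasing")

    def volume_at_dose(self, dose_gy: float) -> float:
        """V(D): % volume receiving at least ``dose_gy``."""
        return float(np.interp(dose_gy, self.edges_gy, self.cum_volume_pct))

    def dose_at_volume(self, volume_pct: float) -> float:
        """D(V): minimum dose to the hottest ``volume_pct`` % (e.g. D95)."""
        v = self.cum_volume_pct
        e = self.edges_gy
        return float(np.interp(-volume_pct, -v, e))

    def mean_dose(self) -> float:
        # mean of the underlying differential distribution
        dv = -np.diff(np.append(self.cum_volume_pct, 0.0)) / 100.0
        centres = np.append((self.edges_gy[:-1] + self.edges_gy[1:]) / 2.0,
                            self.edges_gy[-1])
        return float((dv * centres).sum())


def compute_dvh(dose: ImageVolume, structures: StructureSet,
                bin_width_gy: float = 0.1) -> dict:
    """Cumulative DVH per named structure on a shared grid."""
    if tuple(dose.shape) != tuple(structures.shape) or \
            not np.allclose(dose.affine, structures.affine, atol=1e-6):
        raise GridMismatchError("dose and structures must share a grid")
    dmax = float(dose.voxels.max())
    n_bins = max(int(np.ceil(dmax / bin_width_gy)) + 2, 2)
    edges = np.arange(n_bins + 1) * bin_width_gy
    curves = {}
    for name in structures.names.values():
        m = structures.mask(name)
        if not m.any():
            continue
        vals = dose.voxels[m]
        hist, _ = np.histogram(vals, bins=edges)
        cum = 100.0 * (hist.sum() - np.cumsum(hist)) / hist.sum()
        cum = np.concatenate([[100.0], cum])
        curves[name] = DVHCurve(name, edges, cum)
    return curves


def dvh_table(curves: dict) -> pd.DataFrame:
    """Long-format table (structure, bin_gy, cum_vol_pct) for CSV export."""
    rows = []
    for name, c in curves.items():
        for e, v in zip(c.edges_gy, c.cum_volume_pct):
            rows.append((name, float(e), float(v)))
    return pd.DataFrame(rows, columns=["structure", "bin_gy", "cum_vol_pct"])


def low_dose_volume_fraction(dose: ImageVolume, mask: np.ndarray,
                             lo_gy: float = 0.05, hi_gy: float = 5.0) -> float:
    """Fraction of a structure's volume exposed to the low-dose range
    (lo, hi] Gy — the bath of scattered-through arcs."""
    vals = dose.voxels[np.asarray(mask, bool)]
    return float(((vals > lo_gy) & (vals <= hi_gy)).mean())


# ---------------------------------------------------------------------------
# Targeting-accuracy evaluation
# ---------------------------------------------------------------------------

@dataclass
class TargetingReport:
    """Offsets between the intended (cross-beam) target centre and the
    delivered (arc) dose-region centre, per run and aggregated."""

    offsets_mm: list = field(default_factory=list)
    offsets_vox: list = field(default_factory=list)
    target_centres: list = field(default_factory=list)
    delivered_centres: list = field(default_factory=list)
    voxel_size_mm: float = float("nan")

    @property
    def mean_mm(self) -> float:
        return float(np.mean(self.offsets_mm))

    @property
    def sd_mm(self) -> float:
        return float(np.std(self.offsets_mm, ddof=1)) if len(self.offsets_mm) > 1 else 0.0

    def add(self, target_centre, delivered_centre, voxel_size_mm: float):
        t = np.asarray(target_centre, float)
        d = np.asarray(delivered_centre, float)
        off = float(np.linalg.norm(d - t))
        self.offsets_mm.append(off)
        self.offsets_vox.append(off / voxel_size_mm)
        self.target_centres.append(t.tolist())
        self.delivered_centres.append(d.tolist())
        self.voxel_size_mm = voxel_size_mm

    def summary(self) -> dict:
        return {"n": len(self.offsets_mm),
                "mean_offset_mm": self.mean_mm,
                "sd_offset_mm": self.sd_mm,
                "mean_offset_vox": float(np.mean(self.offsets_vox)),
                "sd_offset_vox": (float(np.std(self.offsets_vox, ddof=1))
                                  if len(self.offsets_vox) > 1 else 0.0),
                "offsets_mm": list(map(float, self.offsets_mm)),
                "voxel_size_mm": self.voxel_size_mm}


def segment_dose_region(dose_est: np.ndarray, threshold_gy: float,
                        affine: np.ndarray) -> np.ndarray:
    """Centroid (world mm) of the largest connected component above a dose
    threshold in a voxelwise dose estimate."""
    from scipy import ndimage

    mask = dose_est > threshold_gy
    if not mask.any():
        raise ReadoutError(f"no region above {threshold_gy:.2f} Gy in the readout")
    lab, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    c = np.argwhere(mask).mean(0)
    A = np.asarray(affine)
    return c @ A[:3, :3].T + A[:3, 3]


def evaluate_targeting(pre_mr: ImageVolume, mid_mr: ImageVolume,
                       post_mr: ImageVolume,
                       response=None,
                       cross_plateau_gy: float = 2.0,
                       arc_dose_gy: float = 4.0,
                       report: TargetingReport | None = None) -> TargetingReport:
    """Score one gel run: offset between the cross-beam intersection centre
    and the delivered arc high-dose centre, both segmented from the virtual
    gel readouts.

    ``pre_mr`` is the pristine gel scan, ``mid_mr`` after target formation,
    ``post_mr`` after the arc treatment.  Doses are recovered by inverting
    the gel response; regions are thresholded midway between the
    single-beam plateau and the summed/arc plateau.
    """
    from .phantoms.readout import invert_gel_response

    d_target = invert_gel_response(pre_mr, mid_mr, response)
    d_total = invert_gel_response(pre_mr, post_mr, response)
    d_arc = np.clip(d_total - d_target, 0.0, None)

    thr_cross = 1.5 * cross_plateau_gy
    thr_arc = 0.5 * arc_dose_gy
    c_target = segment_dose_region(d_target, thr_cross, pre_mr.affine)
    c_arc = segment_dose_region(d_arc, thr_arc, pre_mr.affine)

    report = report if report is not None else TargetingReport()
    report.add(c_target, c_arc, float(np.mean(pre_mr.spacing)))
    return report
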