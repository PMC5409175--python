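"""Modality-independent neighbourhood descriptor (MIND) and a demons-style
deformable registration that minimises descriptor SSD.

The descriptor encodes local self-similarity: for each voxel, the
Gaussian-patch distance to each of its six face neighbours, mapped through
``exp(-D/V)`` with a per-voxel variance estimate ``V``, then normalised so
the largest component is 1.  Because only intensity *differences within
the image* enter, the descriptor is invariant to affine intensity
rescaling, which is what makes SSD between the descriptors of an MR and a
CT volume a meaningful cross-modality match criterion.

The deformable stage is a diffusion-regularised (demons-like) multichannel
SSD minimisation over a coarse-to-fine pyramid: at each iteration the
descriptor residual is projected onto the local descriptor gradient to get
a force, the displacement update is capped at half a voxel, and the field
is Gaussian-smoothed (the diffusion regulariser).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, zoom

from ..image import ImageVolume
from ..transforms import DeformationField

SIX_NEIGHBOURHOOD = ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                     (0, -1, 0), (0, 0, 1), (0, 0, -1))


class ConvergenceError(RuntimeError):
    """Objective increased persistently; the registration diverged."""


@dataclass
class MINDDescriptor:
    """Per-voxel self-similarity vector, shape ``(*image.shape, len(stencil))``."""

    descriptors: np.ndarray
    sigma_vox: float
    stencil: tuple

    def __post_init__(self):
        d = self.descriptors
        if np.any(d <= 0) or np.any(d > 1.0 + 1e-12):
            raise ValueError("descriptor components must lie in (0, 1]")


def mind_descriptor(volume: ImageVolume | np.ndarray, sigma_vox: float = 0.8,
                    stencil=SIX_NEIGHBOURHOOD) -> MINDDescriptor:
    """Compute MIND over a Gaussian patch of ``sigma_vox`` voxels.

    The per-voxel variance normaliser is the mean of the patch distances
    over the stencil, floored at ``1e-6 * dynamic_range**2`` so constant
    regions stay well defined.
    """
    if sigma_vox <= 0:
        raise ValueError("patch sigma must be > 0")
    img = volume.voxels if isinstance(volume, ImageVolume) else np.asarray(volume)
    img = img.astype(float)
    dists = _patch_distances(img, sigma_vox, stencil)
    rng2 = float(img.max() - img.min()) ** 2
    V = np.mean(dists, axis=-1)
    V = np.maximum(V, max(1e-6 * rng2, 1e-300))
    M = np.exp(-dists / V[..., None])
    M /= M.max(axis=-1, keepdims=True)
    return MINDDescriptor(M, sigma_vox, tuple(stencil))


def _patch_distances(img: np.ndarray, sigma_vox: float, stencil) -> np.ndarray:
    out = np.empty((*img.shape, len(stencil)))
    for i, off in enumerate(stencil):
        shifted = np.roll(img, shift=[-o for o in off], axis=(0, 1, 2))
        # edge rolls wrap around; replicate the border instead
        shifted = _fix_roll_border(shifted, img, off)
        out[..., i] = gaussian_filter((img - shifted) ** 2, sigma_vox)
    return out


def _fix_roll_border(shifted: np.ndarray, img: np.ndarray, off) -> np.ndarray:
    sl = [slice(None)] * 3
    for ax, o in enumerate(off):
        if o == 0:
            continue
        s = sl.copy()
        s[ax] = slice(-1, None) if o > 0 else slice(0, 1)
        shifted[tuple(s)] = img[tuple(s)]
    return shifted


# ---------------------------------------------------------------------------
# Deformable registration
# ---------------------------------------------------------------------------

def deformable_register_mind(moving: ImageVolume, fixed: ImageVolume,
                             levels: int = 3, alpha: float = 0.1,
                             iterations: int = 50, sigma_vox: float = 0.8,
                             step_vox: float = 0.5,
                             presmooth_vox: float = 1.0,
                             model: str = "free",
                             poly_degree: int = 2,
                             roi: np.ndarray | None = None,
                             divergence_tol: float = 0.05) -> DeformationField:
    """Deformably register rigidly pre-aligned volumes via MIND SSD.

    Returns a dense :class:`DeformationField` on the fixed grid (pull-back
    convention: resampling ``moving`` with the field reproduces ``fixed``).
    ``alpha`` scales the diffusion regularisation (field smoothing sigma in
    voxels is ``1 + 10 * alpha``).  The multi-resolution objective must be
    non-increasing; an increase above ``divergence_tol`` persisting to the
    end of a level raises :class:`ConvergenceError`.

    ``model`` selects the displacement-field class: ``'free'`` for the
    general diffusion-regularised dense field (multi-resolution demons),
    or ``'polynomial'`` for a global low-order polynomial field
    (Gauss-Newton in coefficient space, single full-resolution pass).
    The polynomial model is the right prior for scanner geometric
    distortion, which is a smooth gradient-nonlinearity / susceptibility
    effect spanning the field of view; it pools descriptor evidence over
    the whole volume so noise averages out and the field cannot drift in
    regions without contrast, but it cannot represent local organ motion
    — use ``'free'`` for that.

    ``roi`` (optional boolean mask on the fixed grid) restricts the
    evidence to structures known to appear in both modalities, e.g. a
    shell around the body outline; without it, strong one-sided edges
    (visible in only one modality) can bias the fit by a fraction of a
    voxel even under the robust reweighting.
    """
    if model not in ("free", "polynomial"):
        raise ValueError(f"unknown field model {model!r}")
    mov = _resample_to(moving, fixed)
    fix = fixed.voxels.astype(float)
    # consistent presmoothing: makes the extra smoothing a warp's
    # interpolation introduces negligible, so descriptor SSD compares
    # alignment rather than noise texture
    if presmooth_vox > 0:
        mov = gaussian_filter(mov, presmooth_vox)
        fix = gaussian_filter(fix, presmooth_vox)
    smooth_sig = 1.0 + 10.0 * alpha

    if model == "polynomial":
        wmask = (np.ones(fix.shape) if roi is None
                 else np.asarray(roi, dtype=float))
        if wmask.shape != fix.shape:
            raise ValueError("roi must live on the fixed grid")
        u = _register_level_poly(mov, fix, np.zeros((*fix.shape, 3)),
                                 min(iterations, 25), sigma_vox, step_vox,
                                 poly_degree, wmask)
    else:
        u = None  # displacement in fixed-grid index units
        for level in range(levels - 1, -1, -1):
            factor = 2 ** level
            fix_l = _downsample(fix, factor)
            mov_l = _downsample(mov, factor)
            if u is None:
                u = np.zeros((*fix_l.shape, 3))
            else:
                u = _upsample_field(u, fix_l.shape)
            u = _register_level(mov_l, fix_l, u, iterations, sigma_vox,
                                smooth_sig, step_vox, divergence_tol)
    # convert index-space displacements to world mm on the fixed grid
    disp_mm = u @ fixed.affine[:3, :3].T
    return DeformationField(disp_mm, fixed.affine.copy())


def mind_ssd(a: ImageVolume | np.ndarray, b: ImageVolume | np.ndarray,
             sigma_vox: float = 0.8) -> float:
    """Mean squared MIND-descriptor difference between two volumes."""
    da = mind_descriptor(a, sigma_vox).descriptors
    db = mind_descriptor(b, sigma_vox).descriptors
    return float(np.mean((da - db) ** 2))


def _resample_to(moving: ImageVolume, fixed: ImageVolume) -> np.ndarray:
    from ..image import resample

    if moving.same_grid(fixed):
        return moving.voxels.astype(float)
    return resample(moving, None, fixed, interpolation="linear").voxels


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    sm = gaussian_filter(img, factor / 2.0)
    return zoom(sm, 1.0 / factor, order=1)


def _upsample_field(u: np.ndarray, shape) -> np.ndarray:
    factors = [t / s for t, s in zip(shape, u.shape[:3])]
    out = np.empty((*shape, 3))
    for c in range(3):
        out[..., c] = zoom(u[..., c], factors, order=1) * factors[c]
    return out


def _warp(img: np.ndarray, u: np.ndarray) -> np.ndarray:
    idx = np.indices(img.shape).astype(float)
    coords = idx + np.moveaxis(u, -1, 0)
    return map_coordinates(img, coords, order=1, mode="nearest")


def _poly_basis(shape, degree: int) -> np.ndarray:
    """Monomial basis of total degree <= degree over normalised [-1,1]
    grid coordinates, shape (*grid, n_terms)."""
    q = [np.linspace(-1.0, 1.0, n) for n in shape]
    X, Y, Z = np.meshgrid(*q, indexing="ij")
    terms = []
    for i in range(degree + 1):
        for j in range(degree + 1 - i):
            for k in range(degree + 1 - i - j):
                terms.append((X ** i) * (Y ** j) * (Z ** k))
    return np.stack(terms, axis=-1)


def _register_level_poly(mov, fix, u, iterations, sigma_vox, step_vox,
                         poly_degree, wmask=None):
    """Gauss-Newton fit of a global polynomial displacement field.

    Unknowns are the 3 x n_terms monomial coefficients; each iteration
    linearises the multichannel descriptor residual around the current
    warp and solves damped, robustly reweighted normal equations.  The
    global fit pools evidence over the whole (or ROI-masked) volume, so
    image noise averages out and the field cannot drift in regions
    without contrast.  Cauchy IRLS weights suppress structures visible in
    only one modality (one-sided edges), whose persistent residuals would
    otherwise bias the minimiser by a fraction of a voxel.
    """
    basis = _poly_basis(fix.shape, poly_degree)
    nt = basis.shape[-1]
    B = basis.reshape(-1, nt)
    Mf = mind_descriptor(fix, sigma_vox).descriptors
    nc = Mf.shape[-1]
    wm = (np.ones(fix.size) if wmask is None
          else np.asarray(wmask, dtype=float).reshape(-1))
    best = (np.inf, u)
    for _ in range(iterations):
        warped = _warp(mov, u)
        Mw = mind_descriptor(warped, sigma_vox).descriptors
        resid = (Mw - Mf).reshape(-1, nc)
        r2 = (resid ** 2).sum(1)
        obj = float((r2 * wm).sum() / max(wm.sum(), 1.0) / nc)
        if obj < best[0]:
            best = (obj, u)
        sel = (wm > 0) & (r2 > 0)
        kappa2 = 4.0 * float(np.median(r2[sel])) if sel.any() else 1.0
        wts = wm / (1.0 + r2 / kappa2)
        A = np.zeros((3 * nt, 3 * nt))
        rhs = np.zeros(3 * nt)
        for c in range(nc):
            g = np.stack(np.gradient(Mw[..., c]), axis=-1).reshape(-1, 3)
            J = np.hstack([g[:, [i]] * B for i in range(3)])   # N x 3nt
            Jw = J * wts[:, None]
            A += J.T @ Jw
            rhs += Jw.T @ resid[:, c]
        lam = 3e-3 * np.trace(A) / A.shape[0]
        delta = np.linalg.solve(A + lam * np.eye(A.shape[0]), -rhs)
        du = np.stack([(B @ delta[i * nt:(i + 1) * nt]).reshape(fix.shape)
                       for i in range(3)], axis=-1)
        # trust region on the step where the evidence lives — the
        # polynomial extrapolates freely at the FOV corners, and capping
        # on that harmless overshoot would throttle convergence
        mag = np.linalg.norm(du, axis=-1).reshape(-1)
        pos = wts > 0.5 * (wts[wts > 0].mean() if (wts > 0).any() else 0.0)
        peak = float(np.percentile(mag[pos], 99)) if pos.any() else mag.max()
        if peak > 2.0 * step_vox:
            du *= 2.0 * step_vox / peak
        u = u + du
        if peak < 1e-4:
            break
    warped = _warp(mov, u)
    resid = (mind_descriptor(warped, sigma_vox).descriptors - Mf).reshape(-1, nc)
    obj = float(((resid ** 2).sum(1) * wm).sum() / max(wm.sum(), 1.0) / nc)
    return u if obj <= best[0] else best[1]


def _register_level(mov, fix, u, iterations, sigma_vox, smooth_sig,
                    step_vox, divergence_tol):
    """Demons-style iteration on one pyramid level.

    The force projects the descriptor residual onto the *fixed* image's
    descriptor gradients (precomputed once; Thirion's choice), with a
    per-voxel step cap; the update is fluid-smoothed before and the field
    diffusion-smoothed (or polynomial-projected) after accumulation.
    """
    Mf = mind_descriptor(fix, sigma_vox).descriptors
    Gf = [np.stack(np.gradient(Mf[..., c]), axis=-1) for c in range(Mf.shape[-1])]
    den = sum(np.einsum("...i,...i->...", g, g) for g in Gf)
    den_reg = den + np.mean(den) + 1e-12
    best = np.inf
    diverged_at_end = False
    obj = np.inf
    u_best = u
    for _ in range(iterations):
        warped = _warp(mov, u)
        Mw = mind_descriptor(warped, sigma_vox).descriptors
        resid = Mw - Mf                              # (*shape, C)
        obj = float(np.mean(resid ** 2))
        if obj > best * (1.0 + divergence_tol):
            diverged_at_end = True
        else:
            diverged_at_end = False
            if obj < best:
                best = obj
                u_best = u

        num = np.zeros((*fix.shape, 3))
        for c, g in enumerate(Gf):
            num += resid[..., c][..., None] * g
        force = -num / den_reg[..., None]
        # per-voxel step cap keeps every update meaningful without letting
        # any single noisy voxel jump
        mag = np.linalg.norm(force, axis=-1)
        scale = np.minimum(1.0, step_vox / np.maximum(mag, 1e-12))
        force *= scale[..., None]
        for c3 in range(3):                          # fluid regularisation
            force[..., c3] = gaussian_filter(force[..., c3], 1.0)
        u = u + force
        for c3 in range(3):                          # diffusion regularisation
            u[..., c3] = gaussian_filter(u[..., c3], smooth_sig)
    if diverged_at_end:
        raise ConvergenceError(
            f"descriptor SSD increased by more than {divergence_tol:.0%} and "
            f"did not recover by the end of the level (last={obj:.3e}, "
            f"best={best:.3e})")
    return u_best if best < obj else u
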