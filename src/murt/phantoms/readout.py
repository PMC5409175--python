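"""Virtual polymer-gel dosimeter readout.

Absorbed dose polymerises the gel; the polymer raises R2 so the readout MR
signal *drops* where dose was deposited.  The response is a saturating
exponential (see :class:`~murt.phantoms.gel.GelResponse`), which keeps a
2 Gy beam path, a 4 Gy beam intersection and unirradiated gel separable as
three intensity classes.
"""

from __future__ import annotations

import numpy as np

from ..image import GridMismatchError, ImageVolume
from .gel import MR_GEL, GelResponse


def gel_mr_after_dose(mr: ImageVolume, dose: ImageVolume,
                      response: GelResponse | None = None,
                      gel_reference_signal: float = MR_GEL) -> ImageVolume:
    """Render the post-irradiation MR of a gel given the absorbed dose.

    ``dose`` must live on the MR grid (resample it first).  The signal
    change is weighted by the local gel fraction (signal relative to
    ``gel_reference_signal``) so dose deposited in air leaves the
    background untouched.  Zero dose returns the input unchanged.
    """
    response = response or GelResponse()
    if not mr.same_grid(dose):
        raise GridMismatchError("dose must be resampled onto the MR grid first")
    d = np.asarray(dose.voxels, dtype=float)
    if np.any(d < -1e-9):
        raise ValueError("dose must be non-negative")
    change = response.signal_change(d)
    gel_frac = np.clip(mr.voxels / gel_reference_signal, 0.0, 1.0)
    out = np.maximum(mr.voxels - change * gel_frac, 0.0)
    return mr.with_voxels(out)


def invert_gel_response(pre: ImageVolume, post: ImageVolume,
                        response: GelResponse | None = None,
                        gel_reference_signal: float = MR_GEL) -> np.ndarray:
    """Estimate the dose (Gy) deposited between two gel readouts.

    Inverts the saturating response on the pre/post signal drop; valid in
    the gel interior where the gel fraction is ~1.
    """
    response = response or GelResponse()
    if not pre.same_grid(post):
        raise GridMismatchError("pre and post readouts must share a grid")
    gel_frac = np.clip(pre.voxels / gel_reference_signal, 1e-3, 1.0)
    change = (pre.voxels - post.voxels) / gel_frac
    return response.dose_from_change(np.clip(change, 0.0, None))
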