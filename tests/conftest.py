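"""Shared fixtures: small phantoms reused across the suite.

All fixtures are deterministic (fixed seeds) and session-scoped where the
underlying data is never mutated.
"""

import numpy as np
import pytest

from murt.image import Grid, ImageVolume, Modality
from murt.phantoms import (GelPhantomSpec, MousePhantomSpec, make_gel_phantom,
                           make_mouse_phantom, voxelize_structures)


@pytest.fixture(scope="session")
def gel_small():
    """Gel phantom at test resolution (CT 0.3 mm, MR 0.4 mm)."""
    spec = GelPhantomSpec(ct_spacing_mm=0.3, mr_spacing_mm=0.4, seed=1,
                          margin_mm=4.0)
    ct, mr, truth = make_gel_phantom(spec)
    return {"spec": spec, "ct": ct, "mr": mr, "truth": truth}


@pytest.fixture(scope="session")
def mouse_small():
    """Mouse phantom at 0.5 mm isotropic (all modalities on one grid)."""
    spec = MousePhantomSpec(ct_spacing_mm=0.5, mr_spacing_mm=0.5, seed=2)
    ct, bssfp, cpmg, truth = make_mouse_phantom(spec)
    truth_mr = voxelize_structures(spec, Grid.of(bssfp), check=False)
    return {"spec": spec, "ct": ct, "bssfp": bssfp, "cpmg": cpmg,
            "truth": truth, "truth_mr": truth_mr}


@pytest.fixture(scope="session")
def water_ct():
    """Homogeneous water-equivalent cylinder on a 30 mm cube at 0.4 mm."""
    g = Grid.from_extent((-15, -15, -15), (15, 15, 15), 0.4)
    vox = np.full(g.shape, 1000.0)
    return ImageVolume(vox, g.affine, Modality.CT)


@pytest.fixture(scope="session")
def air_ct():
    g = Grid.from_extent((-15, -15, -15), (15, 15, 15), 0.4)
    return ImageVolume(np.zeros(g.shape), g.affine, Modality.CT)
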