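"""Transform transfer between co-acquired MR contrasts.

A high-contrast acquisition (bSSFP) drives the MR-to-CT registration; the
resulting chain is then applied unchanged to a second contrast (CPMG)
acquired in the same scanner session, whose frame relative to the first is
either identity or a known fixed rigid offset.  The output lands on the CT
grid, so downstream planning can treat it interchangeably with the CT.
"""

from __future__ import annotations

import numpy as np

from ..image import Grid, ImageVolume, resample
from ..transforms import DeformationField, RigidTransform


class FrameMismatchError(ValueError):
    """The two MR contrasts do not share (or declare) a scanner frame."""


def transfer_transform(chain, target: ImageVolume,
                       ct_grid: ImageVolume | Grid,
                       relative: RigidTransform | None = None,
                       frame_check: ImageVolume | None = None) -> ImageVolume:
    """Resample ``target`` (e.g. CPMG) onto the CT grid through a
    registration ``chain`` found for a sibling contrast (e.g. bSSFP).

    ``chain`` is a single transform or a list applied in order; rigid
    entries map MR-world to CT-world, a trailing :class:`DeformationField`
    must live on the CT grid.  ``relative`` is the fixed rigid map from the
    target's frame to the sibling's frame (identity when both contrasts
    share the scanner frame).  If ``frame_check`` (the sibling volume) is
    given and declares a different frame tag than ``target``, the transfer
    is refused.
    """
    if frame_check is not None and frame_check.frame != target.frame and relative is None:
        raise FrameMismatchError(
            f"target frame {target.frame!r} differs from the registration "
            f"source frame {frame_check.frame!r} and no relative transform "
            "was declared")
    transforms = list(chain) if isinstance(chain, (list, tuple)) else [chain]
    if relative is not None:
        transforms = [relative] + transforms

    rigid = RigidTransform.identity()
    field = None
    for t in transforms:
        if isinstance(t, RigidTransform):
            if field is not None:
                raise ValueError("rigid transform after deformation field is unsupported")
            rigid = t.compose(rigid)
        elif isinstance(t, DeformationField):
            if field is not None:
                raise ValueError("only one deformation field per chain is supported")
            field = t
        else:
            raise TypeError(f"unsupported chain element {type(t)!r}")

    grid = Grid.of(ct_grid) if isinstance(ct_grid, ImageVolume) else ct_grid
    if field is None:
        out = resample(target, rigid, grid)
    else:
        if field.shape != tuple(grid.shape) or not np.allclose(
                field.grid_affine, grid.affine, atol=1e-6):
            raise ValueError("deformation field must live on the CT grid")
        # compose pull-back: CT point x samples target at R^-1(x + u(x))
        ii = np.indices(grid.shape).reshape(3, -1).T.astype(float)
        world = ii @ grid.affine[:3, :3].T + grid.affine[:3, 3]
        src = rigid.inverse().apply(world + field.displacements.reshape(-1, 3))
        from scipy.ndimage import map_coordinates

        idx = target.world_to_index(src)
        vox = map_coordinates(target.voxels.astype(float), idx.T, order=1,
                              mode="constant", cval=0.0).reshape(grid.shape)
        out = ImageVolume(vox, np.asarray(grid.affine).copy(), target.modality)
    # flag for planning import: downstream tools may treat this volume as
    # if it were the planning CT (same grid, same frame)
    out.frame = "ct_planning"
    return out
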