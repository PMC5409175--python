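"""Rigid intensity-based registration (multi-resolution, MI or MIND-SSD).

Cross-modality MR-to-CT alignment uses Mattes mutual information with 32
bins over a 3-level pyramid; the optimisation itself is delegated to
SimpleITK's registration framework.  The MIND-SSD metric registers the
volumes' modality-independent neighbourhood descriptors channelwise with
a mean-squares metric, which is useful when MI's intensity histograms are
too flat to drive the alignment.
"""

from __future__ import annotations

import numpy as np
import SimpleITK as sitk

from ..image import ImageVolume, _to_sitk
from ..transforms import RigidTransform


class InitializationError(ValueError):
    """Volumes do not overlap; registration cannot be initialized."""


def _check_overlap(moving: ImageVolume, fixed: ImageVolume) -> None:
    def box(v):
        corners = np.array([[i, j, k] for i in (0, v.shape[0] - 1)
                            for j in (0, v.shape[1] - 1)
                            for k in (0, v.shape[2] - 1)], dtype=float)
        w = v.index_to_world(corners)
        return w.min(0), w.max(0)

    lo_m, hi_m = box(moving)
    lo_f, hi_f = box(fixed)
    if np.any(hi_m < lo_f) or np.any(hi_f < lo_m):
        raise InitializationError("moving and fixed fields of view do not overlap")


def rigid_register_intensity(moving: ImageVolume, fixed: ImageVolume,
                             metric: str = "MI", levels: int = 3,
                             sampling_fraction: float = 0.2,
                             seed: int = 12345) -> RigidTransform:
    """Recover the rigid map from moving-world to fixed-world.

    ``metric`` is ``'MI'`` (Mattes mutual information, the cross-modality
    default) or ``'MIND-SSD'``.  The returned transform satisfies the
    toolkit's convention ``y_fixed = R @ x_moving + t``.
    """
    _check_overlap(moving, fixed)
    if metric.upper() == "MIND-SSD":
        from .mind import mind_descriptor

        dm = mind_descriptor(moving)
        df = mind_descriptor(fixed)
        # register the first descriptor channel pair with mean squares;
        # remaining channels agree up to the common rigid map
        moving = moving.with_voxels(dm.descriptors[..., 0])
        fixed = fixed.with_voxels(df.descriptors[..., 0])
        metric_name = "ms"
    else:
        metric_name = "mi"

    f = _to_sitk(fixed)
    m = _to_sitk(moving)
    reg = sitk.ImageRegistrationMethod()
    if metric_name == "mi":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    else:
        reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(sampling_fraction, seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=200,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-6)
    reg.SetOptimizerScalesFromPhysicalShift()
    shrink = [2 ** (levels - 1 - i) for i in range(levels)]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel(list(reversed(range(levels))))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    init = sitk.CenteredTransformInitializer(
        f, m, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)
    reg.SetInitialTransform(init, inPlace=False)
    final = reg.Execute(f, m)

    # sitk resampling transforms map fixed-world -> moving-world; invert to
    # get the physical moving -> fixed map
    if isinstance(final, sitk.CompositeTransform):
        final = final.GetNthTransform(0)
    e = sitk.Euler3DTransform(final.Downcast() if hasattr(final, "Downcast") else final)
    R = np.asarray(e.GetMatrix()).reshape(3, 3)
    c = np.asarray(e.GetCenter())
    t = np.asarray(e.GetTranslation())
    offset = c - R @ c + t
    fixed_to_moving = RigidTransform(R, offset)
    return fixed_to_moving.inverse()
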