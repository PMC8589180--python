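"""Longitudinal analysis: SCP-driven elastic registration, EZ change maps,
and chance-normalized predictive values.

Follow-up scans are aligned to baseline by registering the SCP angiograms
(rigid/affine initialization followed by B-spline free-form refinement,
mean-squared-error metric); the recovered transform is then applied to the
photoreceptor masks.  New EZ loss and EZ recovery are the set differences
of the registered follow-up and baseline EZ masks.  The predictive value
of baseline IZ loss for new EZ loss is chance-normalized:

    rPPV = PPV / prevalence        rNPV = NPV / (1 - prevalence)

so a value of 1 means no better than chance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .types import BinaryMask, EnFaceImage, as_mask, check_same_geometry

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegistrationConfig:
    """Knobs of the affine + B-spline registration.

    ``mesh_size`` is the B-spline control grid (per axis, excluding the
    border nodes); ``max_displacement_px`` bounds the returned field as a
    sanity check on convergence.
    """

    mesh_size: int = 6
    affine_iterations: int = 120
    bspline_iterations: int = 40
    shrink_factors: tuple[int, ...] = (4, 2)
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0)
    max_displacement_px: float = 30.0


def _to_sitk(img: EnFaceImage) -> sitk.Image:
    return sitk.GetImageFromArray(img.normalized())


def register_scp(
    baseline: EnFaceImage,
    followup: EnFaceImage,
    config: RegistrationConfig | None = None,
) -> np.ndarray:
    """Estimate the dense displacement aligning follow-up to baseline.

    Returns a ``(2, H, W)`` field ``(dy, dx)`` on the baseline grid: the
    content of baseline pixel ``(y, x)`` is found at follow-up position
    ``(y + dy, x + dx)``.  Pass it to :func:`warp_mask` to bring follow-up
    masks into the baseline frame.

    If the optimized transform fails to improve on the identity in mean
    squared error, a warning is logged and the best field found is still
    returned.
    """
    config = config or RegistrationConfig()
    check_same_geometry(baseline.data, followup.data)
    fixed = _to_sitk(baseline)
    moving = _to_sitk(followup)

    # --- stage 1: affine (captures drift/rotation/scale between visits)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=config.affine_iterations
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(config.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(config.smoothing_sigmas))
    init = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.AffineTransform(2), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg.SetInitialTransform(init, inPlace=True)
    affine = reg.Execute(fixed, moving)

    # --- stage 2: B-spline free-form refinement on top of the affine
    bspline = sitk.BSplineTransformInitializer(fixed, [config.mesh_size, config.mesh_size])
    reg2 = sitk.ImageRegistrationMethod()
    reg2.SetMetricAsMeanSquares()
    reg2.SetInterpolator(sitk.sitkLinear)
    reg2.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=1e-7, numberOfIterations=config.bspline_iterations
    )
    reg2.SetShrinkFactorsPerLevel(list(config.shrink_factors))
    reg2.SetSmoothingSigmasPerLevel(list(config.smoothing_sigmas))
    reg2.SetMovingInitialTransform(affine)
    reg2.SetInitialTransform(bspline, inPlace=True)
    reg2.Execute(fixed, moving)

    composite = sitk.CompositeTransform([affine, bspline])
    field = _transform_to_field(composite, baseline.shape)

    mse_id = float(np.mean((baseline.normalized() - followup.normalized()) ** 2))
    resampled = warp_image(followup, field)
    mse_reg = float(np.mean((baseline.normalized() - resampled.normalized()) ** 2))
    log.debug("registration MSE: identity %.5f -> registered %.5f", mse_id, mse_reg)
    if mse_reg > mse_id:
        log.warning(
            "registration did not improve on identity (MSE %.5f -> %.5f); returning best field",
            mse_id,
            mse_reg,
        )
    max_disp = float(np.hypot(field[0], field[1]).max())
    if max_disp > config.max_displacement_px:
        log.warning("maximum displacement %.1f px exceeds configured bound", max_disp)
    return field


def _transform_to_field(transform: sitk.Transform, shape: tuple[int, int]) -> np.ndarray:
    """Dense (dy, dx) displacement on the fixed grid from a SITK transform
    (unit spacing, so physical = pixel coordinates; SITK x = column)."""
    h, w = shape
    disp = sitk.TransformToDisplacementField(
        transform, sitk.sitkVectorFloat64, [w, h], [0.0, 0.0], [1.0, 1.0], [1.0, 0.0, 0.0, 1.0]
    )
    arr = sitk.GetArrayFromImage(disp)  # (h, w, 2) with components (dx, dy)
    return np.stack([arr[..., 1], arr[..., 0]])


def _resample_through(arr: np.ndarray, field: np.ndarray, order: int, mode: str, cval: float = 0.0) -> np.ndarray:
    h, w = arr.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    coords = np.stack([yy + field[0], xx + field[1]])
    return ndimage.map_coordinates(arr.astype(np.float64), coords, order=order, mode=mode, cval=cval)


def warp_mask(mask: BinaryMask, field: np.ndarray) -> BinaryMask:
    """Resample a follow-up-frame mask into the baseline frame through the
    displacement field (nearest-neighbor; out-of-field pixels background).
    An identity field returns the mask unchanged."""
    mask = as_mask(mask)
    if field.shape != (2, *mask.shape):
        raise ValueError(f"field shape {field.shape} incompatible with mask {mask.shape}")
    return _resample_through(mask.astype(np.float64), field, order=0, mode="constant") > 0.5


def warp_image(img: EnFaceImage, field: np.ndarray) -> EnFaceImage:
    """Linearly resample a follow-up image into the baseline frame."""
    return EnFaceImage(_resample_through(img.data, field, order=1, mode="nearest"), field_mm=img.field_mm)


def ez_change(baseline_ez: BinaryMask, followup_ez_reg: BinaryMask) -> tuple[BinaryMask, BinaryMask]:
    """New EZ loss and EZ recovery between registered timepoints.

    new_loss = follow-up \\ baseline; recovery = baseline \\ follow-up.
    """
    b, f = as_mask(baseline_ez), as_mask(followup_ez_reg)
    check_same_geometry(b, f)
    return f & ~b, b & ~f


@dataclass
class PredictiveValues:
    """Predictive values of baseline IZ loss for new EZ loss within a
    domain Ω, with their chance-normalized counterparts.  Undefined
    quantities (empty predictor class, zero prevalence) are NaN."""

    ppv: float
    npv: float
    prevalence: float
    rppv: float
    rnpv: float
    n_domain_px: int


def predictive_values(
    iz_baseline: BinaryMask, new_ez: BinaryMask, domain: BinaryMask
) -> PredictiveValues:
    """Pixelwise predictive values within Ω = ``domain``.

    PPV = |new ∩ IZ ∩ Ω| / |IZ ∩ Ω| — the chance that a baseline IZ-loss
    pixel develops new EZ loss; NPV = |Ω \\ (IZ ∪ new)| / |Ω \\ IZ| — the
    chance that a pixel without IZ loss stays free of new EZ loss.
    Prevalence is the rate of new EZ loss in Ω; rPPV = PPV/prevalence and
    rNPV = NPV/(1 − prevalence) are 1 when the predictor is no better than
    chance.
    """
    iz, new, dom = as_mask(iz_baseline), as_mask(new_ez), as_mask(domain)
    check_same_geometry(iz, new, dom)
    n_dom = int(np.count_nonzero(dom))
    if n_dom == 0:
        raise ValueError("empty analysis domain")
    new = new & dom
    iz_in = iz & dom
    n_iz = int(np.count_nonzero(iz_in))
    n_new = int(np.count_nonzero(new))

    prevalence = n_new / n_dom
    ppv = int(np.count_nonzero(new & iz_in)) / n_iz if n_iz else math.nan
    n_neg = n_dom - n_iz
    npv = int(np.count_nonzero(dom & ~iz & ~new)) / n_neg if n_neg else math.nan
    rppv = ppv / prevalence if (prevalence > 0 and not math.isnan(ppv)) else math.nan
    rnpv = npv / (1.0 - prevalence) if (prevalence < 1 and not math.isnan(npv)) else math.nan
    return PredictiveValues(ppv=ppv, npv=npv, prevalence=prevalence, rppv=rppv, rnpv=rnpv, n_domain_px=n_dom)


def analysis_domain(
    shape: tuple[int, int], baseline_ez: BinaryMask | None, exclude_baseline_ez: bool = True
) -> BinaryMask:
    """Default analysis domain: the full scan minus baseline EZ loss (new
    loss cannot occur where loss already exists).  Set
    ``exclude_baseline_ez=False`` for the full-scan alternative."""
    dom = np.ones(shape, dtype=bool)
    if exclude_baseline_ez and baseline_ez is not None:
        dom &= ~as_mask(baseline_ez)
    return dom
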