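"""Two-stage MRI-to-CT alignment maximizing normalized mutual information.

Stage 1 fits a 3D rigid transform between the fixed CT and the moving
large-FOV planning MRI by multi-resolution Powell ascent on NMI — the same
:func:`nmi` the package exposes, so the optimizer's objective and the
reported metric are one function. Stage 2 fits a B-spline deformation
between the CT and the rigidly aligned MRI with the metric restricted to
the prostate+rectum region; the fitted deformation is converted to a dense
displacement field windowed to vanish outside the dilated region, so only
the prostate neighbourhood deforms while bones stay put.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import SimpleITK as sitk
from scipy import ndimage, optimize

from .core import EmptyStructureError, GeometryError, VolumeGrid
from .transforms import (
    CompositeTransform,
    DisplacementTransform,
    RigidTransform,
    jacobian_determinant,
    resample_through_transform,
)

log = logging.getLogger(__name__)


class CaptureRangeError(RuntimeError):
    """Raised when the two volumes do not overlap after initialization."""


class UndefinedDiceError(ValueError):
    """Raised when Dice is requested for two empty masks."""


# ---------------------------------------------------------------------------
# Normalized mutual information


def nmi(a: VolumeGrid, b: VolumeGrid, bins: int = 32,
        region: Optional[np.ndarray] = None) -> float:
    """NMI = (H(a) + H(b)) / H(a, b) over the joint histogram; in [1, 2]."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if a.shape != b.shape:
        raise GeometryError("grids must be aligned for NMI")
    av = a.values
    bv = b.values
    if region is not None:
        region = np.asarray(region, dtype=bool)
        if not region.any():
            raise EmptyStructureError("NMI region is empty")
        av = av[region]
        bv = bv[region]
    return _nmi_values(av.ravel(), bv.ravel(), bins)


def _nmi_values(av: np.ndarray, bv: np.ndarray, bins: int) -> float:
    joint, _, _ = np.histogram2d(av, bv, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    def entropy(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    hxy = entropy(p.ravel())
    if hxy == 0.0:
        return 2.0
    return (entropy(px) + entropy(py)) / hxy


# ---------------------------------------------------------------------------
# Stage 1: rigid


@dataclass
class RegistrationConfig:
    bins: int = 32
    shrink_factors: Tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas_mm: Tuple[float, ...] = (4.0, 2.0, 0.0)
    powell_maxiter: Tuple[int, ...] = (4, 3, 2)
    translation_scale_mm: float = 10.0
    rotation_scale_deg: float = 5.0
    # deformable stage
    control_spacing_mm: float = 15.0
    region_dilation_mm: float = 5.0
    bspline_iterations: int = 30
    bspline_shrink: Tuple[int, ...] = (2, 1)


def _downsample(vol: VolumeGrid, factor: int, sigma_mm: float) -> VolumeGrid:
    if factor == 1 and sigma_mm == 0:
        return vol
    vals = vol.values.astype(float)
    if sigma_mm > 0:
        vals = ndimage.gaussian_filter(vals, [sigma_mm / s for s in vol.spacing])
    sl = tuple(slice(None, None, factor) for _ in range(3))
    vals = vals[sl]
    spacing = tuple(s * factor for s in vol.spacing)
    return VolumeGrid(vals, spacing, vol.origin, vol.modality)


def _foreground_centroid(vol: VolumeGrid) -> np.ndarray:
    vals = vol.values.astype(float)
    thr = vals.min() + 0.2 * (vals.max() - vals.min())
    mask = vals > thr
    if not mask.any():
        mask = np.ones_like(mask)
    idx = np.argwhere(mask).mean(axis=0)
    return vol.voxel_to_physical(idx)


@dataclass
class RigidResult:
    transform: RigidTransform
    trace: List[Tuple[int, float]] = field(default_factory=list)
    final_nmi: float = 0.0


def register_rigid(fixed: VolumeGrid, moving: VolumeGrid,
                   config: Optional[RegistrationConfig] = None,
                   metric_region: Optional[np.ndarray] = None) -> RigidResult:
    """Multi-resolution Powell maximization of NMI over 6 rigid parameters.

    Initialized by aligning foreground intensity centroids; the returned
    transform never scores below the initial one on the full-resolution
    metric. ``metric_region`` optionally restricts the fixed voxels entering
    the joint histogram (e.g. a box around the prostate).
    """
    config = config or RegistrationConfig()
    center = _foreground_centroid(fixed)
    t0 = _foreground_centroid(moving) - center
    trace: List[Tuple[int, float]] = []
    mov_vals = moving.values.astype(float)
    mov_min = float(mov_vals.min())
    mov_origin = np.asarray(moving.origin)
    mov_spacing = np.asarray(moving.spacing)

    def level_points(fx: VolumeGrid, region: Optional[np.ndarray]):
        xs, ys, zs = fx.physical_grid()
        if region is None:
            sel = np.ones(fx.shape, dtype=bool)
        else:
            sel = region
        pts = np.stack([xs[sel], ys[sel], zs[sel]], axis=1)
        return pts, fx.values[sel].astype(float).ravel()

    def make_cost(fx: VolumeGrid, region: Optional[np.ndarray]):
        pts, fvals = level_points(fx, region)

        def cost(params):
            tr = RigidTransform.from_params(
                np.asarray(params[:3]) * config.rotation_scale_deg,
                np.asarray(params[3:]) * config.translation_scale_mm,
                tuple(center))
            mapped = tr.apply(pts)
            coords = (mapped - mov_origin) / mov_spacing
            warped = ndimage.map_coordinates(mov_vals, coords.T, order=1,
                                             mode="constant", cval=mov_min)
            return -_nmi_values(fvals, warped, config.bins)
        return cost

    params = np.concatenate([np.zeros(3), t0 / config.translation_scale_mm])
    full_cost = make_cost(fixed, metric_region)
    init_cost_full = full_cost(params)
    if not np.isfinite(init_cost_full) or init_cost_full >= -1.0 + 1e-9:
        raise CaptureRangeError("no informative overlap after centroid initialization")
    for level, (factor, sigma, maxiter) in enumerate(
            zip(config.shrink_factors, config.smoothing_sigmas_mm, config.powell_maxiter)):
        fx = _downsample(fixed, factor, sigma)
        region = None
        if metric_region is not None:
            sl = tuple(slice(None, None, factor) for _ in range(3))
            region = metric_region[sl]
        cost = make_cost(fx, region) if factor != 1 else full_cost
        res = optimize.minimize(cost, params, method="Powell",
                                options={"maxiter": maxiter, "xtol": 1e-3, "ftol": 1e-7})
        params = res.x
        trace.append((level, -float(res.fun)))
        log.info("rigid level %d (shrink %d): NMI %.5f", level, factor, -res.fun)
    transform = RigidTransform.from_params(
        params[:3] * config.rotation_scale_deg,
        params[3:] * config.translation_scale_mm, tuple(center))
    final = -full_cost(params)
    if final < -init_cost_full:  # never return worse than the initialization
        transform = RigidTransform.from_params((0, 0, 0), t0, tuple(center))
        final = -init_cost_full
    return RigidResult(transform, trace, final)


# ---------------------------------------------------------------------------
# Stage 2: B-spline deformable, region-restricted


@dataclass
class BSplineResult:
    transform: DisplacementTransform
    control_spacing_mm: float
    nmi_before: float
    nmi_after: float


def _to_sitk(vol: VolumeGrid) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.astype(np.float64).transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def _region_window(region: np.ndarray, geometry: VolumeGrid, dilation_mm: float) -> np.ndarray:
    """1 inside the region, linear taper to 0 at ``dilation_mm`` outside."""
    dist = ndimage.distance_transform_edt(~region, sampling=geometry.spacing)
    return np.clip(1.0 - dist / max(dilation_mm, 1e-6), 0.0, 1.0)


def register_bspline(fixed: VolumeGrid, moving_aligned: VolumeGrid,
                     metric_region: np.ndarray,
                     config: Optional[RegistrationConfig] = None) -> BSplineResult:
    """Region-restricted B-spline deformable stage.

    ``moving_aligned`` is the moving image already resampled through the
    rigid stage onto the fixed grid. The metric is evaluated only inside
    ``metric_region`` (prostate+rectum); the result is returned as a dense
    displacement field on the fixed grid, windowed to zero outside the
    dilated region, and is discarded (identity) if it does not improve the
    package's own NMI over the region.
    """
    config = config or RegistrationConfig()
    metric_region = np.asarray(metric_region, dtype=bool)
    if not metric_region.any():
        raise EmptyStructureError("metric region is empty")
    nmi_before = nmi(fixed, moving_aligned, config.bins, metric_region)

    # work on a crop around the region: fewer control points, faster metric
    from .core import crop_to_structure, mask_bounding_box

    bounds = mask_bounding_box(metric_region)
    pad = [int(np.ceil(15.0 / s)) for s in fixed.spacing]
    sl = tuple(slice(max(0, b0 - p), min(n, b1 + p + 1))
               for (b0, b1), p, n in zip(bounds, pad, fixed.shape))
    fixed_c = VolumeGrid(fixed.values[sl],
                         fixed.spacing,
                         tuple(fixed.origin[a] + sl[a].start * fixed.spacing[a] for a in range(3)),
                         fixed.modality)
    moving_c = fixed_c.with_values(moving_aligned.values[sl], moving_aligned.modality)
    region_c = metric_region[sl]

    f_img = _to_sitk(fixed_c)
    m_img = _to_sitk(moving_c)
    dil_vox = [max(1, int(np.ceil(config.region_dilation_mm / s))) for s in fixed.spacing]
    region_dil = ndimage.binary_dilation(
        region_c, iterations=1,
        structure=np.ones((2 * dil_vox[0] + 1, 2 * dil_vox[1] + 1, 2 * dil_vox[2] + 1), bool))
    mask_img = sitk.GetImageFromArray(region_dil.astype(np.uint8).transpose(2, 1, 0))
    mask_img.CopyInformation(f_img)

    extent = [sz * sp for sz, sp in zip(f_img.GetSize(), f_img.GetSpacing())]
    mesh = [max(1, int(round(e / config.control_spacing_mm))) for e in extent]
    tx0 = sitk.BSplineTransformInitializer(f_img, mesh, order=3)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=config.bins)
    reg.SetMetricFixedMask(mask_img)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(gradientConvergenceTolerance=1e-7,
                             numberOfIterations=config.bspline_iterations)
    reg.SetInitialTransform(tx0, inPlace=True)
    shrink = list(config.bspline_shrink)
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([1.0] * (len(shrink) - 1) + [0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    try:
        fitted = reg.Execute(f_img, m_img)
    except RuntimeError as exc:  # optimizer failure: fall back to identity
        log.warning("deformable stage failed (%s); returning identity", exc)
        zero = DisplacementTransform.zero(fixed)
        return BSplineResult(zero, config.control_spacing_mm, nmi_before, nmi_before)

    to_field = sitk.TransformToDisplacementFieldFilter()
    to_field.SetReferenceImage(f_img)
    field_img = to_field.Execute(fitted)
    field = sitk.GetArrayFromImage(field_img)  # (z, y, x, 3), components in (x, y, z)
    field = np.ascontiguousarray(field.transpose(2, 1, 0, 3)).astype(float)

    # cap the magnitude at one control spacing (MI has no gradient in flat
    # tissue, where the optimizer can drift), then lightly smooth
    mag = np.linalg.norm(field, axis=-1)
    field *= np.minimum(1.0, config.control_spacing_mm / np.maximum(mag, 1e-9))[..., None]
    for c in range(3):
        field[..., c] = ndimage.gaussian_filter(field[..., c], 1.0)
    window = _region_window(region_c, fixed_c, config.region_dilation_mm)
    field *= window[..., None]

    # guard against folding: smooth until the Jacobian stays positive
    for attempt in range(4):
        if jacobian_determinant(field, fixed_c.spacing).min() > 0:
            break
        log.warning("deformation folds (attempt %d); smoothing the field", attempt + 1)
        for c in range(3):
            field[..., c] = ndimage.gaussian_filter(field[..., c], 1.5)
        field *= window[..., None]
    disp = DisplacementTransform(field, fixed_c.spacing, fixed_c.origin, support=region_dil)

    warped = resample_through_transform(moving_aligned, disp, fixed,
                                        cval=float(moving_aligned.values.min()))
    nmi_after = nmi(fixed, warped, config.bins, metric_region)
    if nmi_after < nmi_before:
        log.warning("deformable stage did not improve NMI (%.5f -> %.5f); using identity",
                    nmi_before, nmi_after)
        disp = DisplacementTransform.zero(fixed)
        nmi_after = nmi_before
    return BSplineResult(disp, config.control_spacing_mm, nmi_before, nmi_after)


# ---------------------------------------------------------------------------
# Transference and evaluation


def transfer(source: VolumeGrid, transform, target: VolumeGrid,
             is_mask: Optional[bool] = None) -> VolumeGrid:
    """Map a probability map or binary mask from MRI space onto the CT grid.

    Probability maps are resampled with linear interpolation (a convex
    combination, so values stay within the source range); masks use nearest
    neighbour. ``transform`` maps target (CT) points to source (MRI) points.
    """
    if is_mask is None:
        is_mask = source.modality == "MASK"
    interp = "nearest" if is_mask else "linear"
    out = resample_through_transform(source, transform, target, interpolation=interp, cval=0.0)
    if source.modality == "PROB":
        out = VolumeGrid(np.clip(out.values, 0.0, 1.0), out.spacing, out.origin, "PROB")
    return out


def dice(a: np.ndarray, b: np.ndarray, slice_restricted: bool = False) -> float:
    """Dice similarity 2|A∩B| / (|A| + |B|).

    With ``slice_restricted`` the coefficient is computed only over slices
    (last axis) where both masks are non-empty, accommodating cases where
    one contour extends over extra slices.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise GeometryError("masks must share a geometry")
    if slice_restricted:
        keep = [k for k in range(a.shape[2]) if a[:, :, k].any() and b[:, :, k].any()]
        if not keep:
            raise UndefinedDiceError("no slice contains both masks")
        a = a[:, :, keep]
        b = b[:, :, keep]
    denom = a.sum() + b.sum()
    if denom == 0:
        raise UndefinedDiceError("Dice is undefined for two empty masks")
    return float(2.0 * np.logical_and(a, b).sum() / denom)


@dataclass
class TransferenceResult:
    rigid: RigidResult
    deformable: BSplineResult
    composite: CompositeTransform
    dice_rigid: float
    dice_deformable: float


def register_case(ct: VolumeGrid, mri_large: VolumeGrid,
                  mri_prostate: np.ndarray, ct_prostate: np.ndarray,
                  ct_rectum: Optional[np.ndarray] = None,
                  config: Optional[RegistrationConfig] = None) -> TransferenceResult:
    """Full two-stage alignment of one case plus prostate Dice evaluation.

    The metric region for the deformable stage is the CT prostate+rectum.
    Dice compares the transferred MRI prostate mask with the CT prostate
    mask after each stage.
    """
    config = config or RegistrationConfig()
    rigid_res = register_rigid(ct, mri_large, config)
    prost_vol = VolumeGrid(mri_prostate.astype(np.uint8), mri_large.spacing,
                           mri_large.origin, "MASK")
    moved_rigid = transfer(prost_vol, rigid_res.transform, ct, is_mask=True)
    d_rigid = dice(moved_rigid.values > 0.5, ct_prostate)

    region = ct_prostate.copy()
    if ct_rectum is not None:
        region = region | ct_rectum
    aligned = resample_through_transform(mri_large, rigid_res.transform, ct,
                                         cval=float(mri_large.values.min()))
    bspl = register_bspline(ct, aligned, region, config)
    composite = CompositeTransform(rigid_res.transform, bspl.transform)
    moved_def = transfer(prost_vol, composite, ct, is_mask=True)
    d_def = dice(moved_def.values > 0.5, ct_prostate)
    return TransferenceResult(rigid_res, bspl, composite, d_rigid, d_def)
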