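"""Rigid and deformable alignment plus volume/structure warping.

Rigid registration is a multi-resolution mean-squared-difference optimisation
(SimpleITK); the returned :class:`~cbctdose.volumes.RigidTransform` maps
fixed-space points into the moving image's space, so resampling the moving
image through it aligns it with the fixed image.  Deformable registration is
demons-style with Gaussian regularisation.  Both accept an injected
ground-truth transform (bypass mode) so downstream analyses can be run with
registration error excluded.
"""

from __future__ import annotations

import warnings

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volumes import (
    DeformationField,
    ImageGrid,
    ROIMask,
    RigidTransform,
    ScalarVolume,
    _DEFAULT_FILL,
    _to_sitk,
)

__all__ = [
    "register_rigid",
    "register_deformable",
    "warp_volume",
    "warp_mask",
    "warp_structures",
    "apply_rigid",
    "apply_rigid_mask",
    "masked_mse",
]


def masked_mse(a: ScalarVolume, b: ScalarVolume, mask: ROIMask | None = None) -> float:
    sel = mask.values if mask is not None else np.ones(a.grid.shape, bool)
    d = a.values[sel] - b.values[sel]
    return float(np.mean(d * d))


def _sample_at_points(
    volume: ScalarVolume, points: np.ndarray, method: str, fill: float | None = None
) -> np.ndarray:
    """Interpolate a volume at world points, shape (..., 3)."""
    if fill is None:
        fill = _DEFAULT_FILL.get(volume.quantity, 0.0)
    idx = volume.grid.world_to_index(points)
    coords = np.moveaxis(idx, -1, 0)
    order = 1 if method == "trilinear" else 0
    return ndimage.map_coordinates(
        volume.values, coords, order=order, mode="constant", cval=fill
    )


def apply_rigid(
    moving: ScalarVolume,
    transform: RigidTransform,
    target: ImageGrid | None = None,
    method: str = "trilinear",
) -> ScalarVolume:
    """Resample the moving volume through a rigid transform onto ``target``."""
    target = target or moving.grid
    X, Y, Z = target.meshgrid()
    pts = np.stack([X, Y, Z], axis=-1)
    out = _sample_at_points(moving, transform.apply(pts), method)
    return ScalarVolume(target, out, moving.quantity)


def apply_rigid_mask(
    mask: ROIMask, transform: RigidTransform, target: ImageGrid | None = None
) -> ROIMask:
    vol = ScalarVolume(mask.grid, mask.values.astype(float), "gamma")
    out = apply_rigid(vol, transform, target, method="nearest")
    return ROIMask(out.grid, out.values > 0.5, mask.name)


def warp_volume(
    volume: ScalarVolume, field: DeformationField, method: str = "trilinear"
) -> ScalarVolume:
    """Pull-back warp: output voxel at x takes the value of ``volume`` at x + u(x)."""
    X, Y, Z = field.grid.meshgrid()
    pts = np.stack([X, Y, Z], axis=-1) + field.displacement
    out = _sample_at_points(volume, pts, method)
    return ScalarVolume(field.grid, out, volume.quantity)


def warp_mask(mask: ROIMask, field: DeformationField) -> ROIMask:
    vol = ScalarVolume(mask.grid, mask.values.astype(float), "gamma")
    out = warp_volume(vol, field, method="nearest")
    return ROIMask(out.grid, out.values > 0.5, mask.name)


def warp_structures(structures, field: DeformationField):
    from .volumes import StructureSet

    return StructureSet(
        {name: warp_mask(m, field) for name, m in structures.masks.items()},
        structures.external,
    )


# ---------------------------------------------------------------------------
# Rigid registration


def register_rigid(
    fixed: ScalarVolume,
    moving: ScalarVolume,
    mask: ROIMask | None = None,
    dof: str = "rigid6",
    ground_truth: RigidTransform | None = None,
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` to ``fixed``.

    ``dof`` selects 6 degrees of freedom (default) or rotation-only ``rot3``.
    Passing ``ground_truth`` bypasses estimation entirely.
    """
    if ground_truth is not None:
        return ground_truth
    if dof not in ("rigid6", "rot3"):
        raise ValueError(f"dof must be 'rigid6' or 'rot3', got {dof!r}")
    lo_f, hi_f = fixed.grid.extent()
    lo_m, hi_m = moving.grid.extent()
    if np.any(hi_f < lo_m) or np.any(hi_m < lo_f):
        raise ValueError("fixed and moving volumes do not overlap")

    f_img = _to_sitk(fixed.values, fixed.grid, np.float32)
    m_img = _to_sitk(moving.values, moving.grid, np.float32)
    center = tuple(0.5 * (np.asarray(fixed.grid.extent()[0]) + fixed.grid.extent()[1]))
    initial = sitk.Euler3DTransform()
    initial.SetCenter(center)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    if mask is not None:
        reg.SetMetricFixedMask(_to_sitk(mask.values.astype(np.uint8), mask.grid, np.uint8))
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetInitialTransform(initial, inPlace=True)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-5, numberOfIterations=300, relaxationFactor=0.6
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    if dof == "rot3":
        reg.SetOptimizerWeights([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    result = reg.Execute(f_img, m_img)

    euler = sitk.Euler3DTransform(result)
    R = np.asarray(euler.GetMatrix()).reshape(3, 3)
    from scipy.spatial.transform import Rotation

    angles = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
    out = RigidTransform(tuple(angles), tuple(euler.GetTranslation()), tuple(euler.GetCenter()))

    # never return something worse than the identity transform; compare on
    # the voxels that stay inside the moving extent under both transforms
    identity = RigidTransform(center=center)
    X, Y, Z = fixed.grid.meshgrid()
    pts = np.stack([X, Y, Z], axis=-1)
    lo_m, hi_m = moving.grid.extent()

    def _valid(t: RigidTransform) -> np.ndarray:
        q = t.apply(pts)
        return np.all((q >= lo_m) & (q <= hi_m), axis=-1)

    sel = _valid(identity) & _valid(out)
    if mask is not None:
        sel &= mask.values
    if not sel.any():
        return identity
    res_id = fixed.values - apply_rigid(moving, identity, fixed.grid).values
    res_out = fixed.values - apply_rigid(moving, out, fixed.grid).values
    return out if np.mean(res_out[sel] ** 2) <= np.mean(res_id[sel] ** 2) else identity


# ---------------------------------------------------------------------------
# Deformable (demons) registration


def _demons_multires(
    f_img: sitk.Image,
    m_img: sitk.Image,
    levels: list[int],
    iterations: int,
    sigma_vox: float,
) -> sitk.Image:
    field = None
    for shrink in levels:
        if shrink > 1:
            f_lvl = sitk.Shrink(f_img, [shrink] * 3)
            m_lvl = sitk.Shrink(m_img, [shrink] * 3)
        else:
            f_lvl, m_lvl = f_img, m_img
        if field is not None:
            field = sitk.Resample(
                field,
                f_lvl,
                sitk.Transform(),
                sitk.sitkLinear,
                0.0,
                sitk.sitkVectorFloat64,
            )
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(iterations)
        # ITK demons regularisation is specified in pixel units
        demons.SetStandardDeviations(sigma_vox)
        demons.SetSmoothDisplacementField(True)
        demons.SetSmoothUpdateField(False)
        if field is None:
            field = demons.Execute(f_lvl, m_lvl)
        else:
            field = demons.Execute(f_lvl, m_lvl, field)
    return field


def register_deformable(
    fixed: ScalarVolume,
    moving: ScalarVolume,
    focus_mask: ROIMask | None = None,
    levels: tuple[int, ...] = (4, 2, 1),
    iterations: int = 50,
    sigma_vox: float = 2.0,
    focus_dilation_mm: float = 15.0,
    ground_truth: DeformationField | None = None,
) -> DeformationField:
    """Demons-style multi-resolution deformable registration.

    Returns a smooth displacement field on the fixed grid (pull-back
    convention) that reduces the masked MSE relative to the identity; the
    field is faded to zero outside a ``focus_dilation_mm`` dilation of the
    focus mask.  ``ground_truth`` bypasses estimation.
    """
    if ground_truth is not None:
        return ground_truth
    f_img = _to_sitk(fixed.values, fixed.grid, np.float32)
    m_img = _to_sitk(moving.values, moving.grid, np.float32)
    field_img = _demons_multires(f_img, m_img, list(levels), iterations, sigma_vox)
    arr = sitk.GetArrayFromImage(field_img)  # (z, y, x, 3) with (x,y,z) components
    disp = np.transpose(arr, (2, 1, 0, 3)).astype(float)
    field = DeformationField(fixed.grid, disp)

    if focus_mask is not None:
        dist = ndimage.distance_transform_edt(
            ~focus_mask.values, sampling=fixed.grid.spacing
        )
        # smooth fade from 1 inside the dilated mask to 0 beyond it
        fade = np.clip(1.0 - dist / max(focus_dilation_mm, 1e-6), 0.0, 1.0)
        field = DeformationField(fixed.grid, field.displacement * fade[..., None])

    mse_id = masked_mse(fixed, moving, focus_mask)
    mse_reg = masked_mse(fixed, warp_volume(moving, field), focus_mask)
    if mse_reg > mse_id:
        warnings.warn(
            "deformable registration did not improve on the identity; "
            "returning the identity field",
            stacklevel=2,
        )
        return DeformationField.identity(fixed.grid)
    return field
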