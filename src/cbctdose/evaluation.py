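"""ROI construction and HU-accuracy metrics against the repeat CT.

The evaluation region ``CBCT-ROI`` is the CBCT field of view eroded by 2 cm,
intersected with the BODY contour; HU accuracy inside it (and inside the
whole-breast CTV) is summarised by the mean absolute error

    MAE = (1/n) sum_i |HU_rCT(i) - HU_syntheticCT(i)|

and the mean (signed) error

    ME  = (1/n) sum_i (HU_rCT(i) - HU_syntheticCT(i)),

where i runs over the n voxels of the ROI and the sign convention is
reference (rCT) minus synthetic.  Cohort comparisons use a two-tailed
pooled-variance (equal-variance) two-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .volumes import ROIMask, ScalarVolume, _require_same_grid, erode_mask, intersect_masks

__all__ = ["HUAccuracyResult", "build_cbct_roi", "mae", "me", "hu_accuracy", "cohort_ttest"]


@dataclass(frozen=True)
class HUAccuracyResult:
    roi: str
    n: int
    mae: float
    me: float
    method: str = ""
    case: str = ""

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("HU accuracy requires a non-empty ROI")
        if self.mae < 0 or self.mae + 1e-9 < abs(self.me):
            raise ValueError("invalid metrics: need MAE >= |ME| >= 0")


def build_cbct_roi(
    fov: ROIMask,
    body: ROIMask,
    margin_mm: float = 20.0,
    in_plane_only: bool = False,
) -> ROIMask:
    """CBCT evaluation ROI: the FOV eroded by ``margin_mm``, intersected with BODY.

    Erosion is 3-D by default (shrinking the cylinder radially and at its
    axial ends); ``in_plane_only`` restricts it to the transverse plane.  The
    ROI is meant to be copied rigidly to every image set so the compared
    volumes are identical.
    """
    _require_same_grid(fov, body)
    if margin_mm == 0:
        eroded = fov
    elif in_plane_only:
        from scipy import ndimage

        dist = np.stack(
            [
                ndimage.distance_transform_edt(fov.values[:, :, k], sampling=fov.grid.spacing[:2])
                for k in range(fov.grid.shape[2])
            ],
            axis=2,
        )
        eroded = ROIMask(fov.grid, dist > margin_mm, fov.name)
    else:
        eroded = erode_mask(fov, margin_mm)
    roi = intersect_masks(eroded, body, name="CBCT_ROI")
    if roi.n_voxels == 0:
        warnings.warn("CBCT-ROI is empty (body outside the eroded FOV)", stacklevel=2)
    return roi


def _masked_diff(ref: ScalarVolume, test: ScalarVolume, roi: ROIMask) -> np.ndarray:
    _require_same_grid(ref, test, roi)
    if roi.n_voxels == 0:
        raise ValueError("metric ROI is empty")
    return ref.values[roi.values] - test.values[roi.values]


def mae(ref: ScalarVolume, test: ScalarVolume, roi: ROIMask) -> float:
    """Mean absolute voxelwise HU error over the ROI."""
    return float(np.mean(np.abs(_masked_diff(ref, test, roi))))


def me(ref: ScalarVolume, test: ScalarVolume, roi: ROIMask) -> float:
    """Mean signed HU error over the ROI (reference minus synthetic)."""
    return float(np.mean(_masked_diff(ref, test, roi)))


def hu_accuracy(
    ref: ScalarVolume,
    test: ScalarVolume,
    roi: ROIMask,
    method: str = "",
    case: str = "",
) -> HUAccuracyResult:
    d = _masked_diff(ref, test, roi)
    return HUAccuracyResult(
        roi=roi.name,
        n=int(d.size),
        mae=float(np.mean(np.abs(d))),
        me=float(np.mean(d)),
        method=method,
        case=case,
    )


def cohort_ttest(values_a, values_b) -> tuple[float, float]:
    """Two-tailed pooled-variance (equal variances) two-sample t-test.

    Degenerate input with zero pooled variance and equal means returns
    (0.0, 1.0) by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
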