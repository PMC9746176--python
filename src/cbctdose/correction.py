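"""CBCT correction methods: HU-override, analytical correction/conversion, virtual CT.

Three routes from a scatter-corrupted CBCT to an image usable for dose
calculation:

* **HU-override (CBCT_HU)** — automatic multilevel (multi-Otsu) thresholding
  of the CBCT grey-level histogram inside BODY ∩ FOV into six tissue classes,
  each assigned a fixed mass density (air 0.00121, lung 0.26, adipose 0.95,
  tissue 1.05, cartilage/bone 1.6, other 3 g/cm^3).  The raw grey levels are
  kept unaltered alongside the class map: HU-accuracy metrics for this method
  are computed on the raw CBCT, only dosimetry uses the class densities.
* **Analytical correction and conversion (CBCT_CC)** — iterates a grey-level
  conversion (joint histogram of the deformed reference CT and the CBCT,
  per-column modal HU, monotonised) with a low-pass shading correction (the
  smooth residual against the deformed CT, restricted to the FOV).
* **Virtual CT (CT_V)** — the reference CT deformed onto the CBCT; only air
  pockets present in either image are replaced with CBCT_CC values, so the
  result equals the warped CT bit-exactly everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.isotonic import IsotonicRegression

from .registration import warp_volume
from .volumes import (
    DeformationField,
    ROIMask,
    ScalarVolume,
    _require_same_grid,
    intersect_masks,
    union_masks,
)

__all__ = [
    "DensityClassTable",
    "ConversionFunction",
    "CorrectedImage",
    "correct_hu_override",
    "estimate_conversion",
    "correct_analytical",
    "detect_air_pockets",
    "build_virtual_ct",
]


@dataclass(frozen=True)
class DensityClassTable:
    """Ordered tissue classes and their mass densities (g/cm^3)."""

    names: tuple[str, ...] = ("air", "lung", "adipose", "tissue", "cartilage/bone", "other")
    densities: tuple[float, ...] = (0.00121, 0.26, 0.95, 1.05, 1.6, 3.0)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.densities):
            raise ValueError("names and densities must have equal length")
        if np.any(np.diff(self.densities) <= 0):
            raise ValueError("class densities must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.densities)


@dataclass
class ConversionFunction:
    """Monotone piecewise-linear CBCT grey level -> CT HU mapping.

    Evaluation is linear interpolation between anchors with clamped
    extrapolation beyond the anchor range.
    """

    anchors_in: np.ndarray  # CBCT grey levels, strictly increasing
    anchors_out: np.ndarray  # CT HU, non-decreasing

    def __post_init__(self) -> None:
        self.anchors_in = np.asarray(self.anchors_in, dtype=float)
        self.anchors_out = np.asarray(self.anchors_out, dtype=float)
        if self.anchors_in.size < 2:
            raise ValueError("conversion function needs at least 2 anchors")
        if np.any(np.diff(self.anchors_in) <= 0):
            raise ValueError("anchor inputs must be strictly increasing")
        if np.any(np.diff(self.anchors_out) < -1e-9):
            raise ValueError("anchor outputs must be non-decreasing")

    def __call__(self, grey: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(grey, dtype=float), self.anchors_in, self.anchors_out)


@dataclass
class CorrectedImage:
    """Output of one correction method.

    ``method`` is ``CBCT_HU``, ``CBCT_CC`` or ``CT_V``.  For ``CBCT_HU`` the
    payload is a class-label volume plus density table (with the raw CBCT
    retained in ``hu``); for the other methods ``hu`` holds corrected HU.
    """

    method: str
    hu: ScalarVolume
    class_labels: np.ndarray | None = None
    density_table: DensityClassTable | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method == "CBCT_HU" and (
            self.class_labels is None or self.density_table is None
        ):
            raise ValueError("CBCT_HU requires class labels and a density table")

    def density_volume(self, hu_to_density=None) -> ScalarVolume:
        """Mass-density volume for dose calculation.

        CBCT_HU maps each voxel's class to its table density; the other
        methods convert their HU through ``hu_to_density`` (a callable or a
        HUDensityTable).
        """
        if self.method == "CBCT_HU":
            dens = np.asarray(self.density_table.densities)[self.class_labels]
            return ScalarVolume(self.hu.grid, dens, "density")
        if hu_to_density is None:
            raise ValueError("HU-valued corrected images need an HU->density table")
        return ScalarVolume(
            self.hu.grid, np.maximum(hu_to_density(self.hu.values), 0.0), "density"
        )


# ---------------------------------------------------------------------------
# HU-override correction


def multiotsu_thresholds(values: np.ndarray, classes: int, bin_width: float = 1.0) -> np.ndarray:
    """Exact multilevel Otsu thresholds on a fixed-resolution histogram.

    Maximises the between-class variance (equivalently ``sum_k w_k mu_k^2``)
    over all threshold placements by dynamic programming on the cumulative
    histogram moments, at ``bin_width`` grey-level resolution (1 HU default).
    Returns ``classes - 1`` thresholds, as bin-edge grey levels.
    """
    v = np.asarray(values, dtype=float).ravel()
    lo, hi = float(v.min()), float(v.max())
    n_bins = int(np.ceil((hi - lo) / bin_width)) + 1
    if n_bins < classes:
        raise ValueError(
            f"cannot place {classes - 1} thresholds: grey-level range spans "
            f"only {n_bins} bins"
        )
    edges = lo + bin_width * np.arange(n_bins + 1)
    hist, _ = np.histogram(v, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    p = np.concatenate([[0.0], np.cumsum(hist)])
    s = np.concatenate([[0.0], np.cumsum(hist * centers)])

    def score(i, j):
        """sum w*mu^2 of the class spanning bins [i, j) (broadcast-friendly)."""
        w = p[j] - p[i]
        m = s[j] - s[i]
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            return np.where(w > 0, m * m / np.maximum(w, 1e-300), 0.0)

    idx = np.arange(n_bins + 1)
    # best[c][j]: max score of splitting bins [0, j) into c classes
    best = score(np.zeros(n_bins + 1, dtype=int), idx)
    cut = np.zeros((classes, n_bins + 1), dtype=int)
    for c in range(1, classes):
        cand = best[:, None] + score(idx[:, None], idx[None, :])
        cand = np.where(idx[:, None] < idx[None, :], cand, -np.inf)  # require i < j
        cut[c] = np.argmax(cand, axis=0)
        best = np.max(cand, axis=0)
    thresholds = np.empty(classes - 1)
    j = n_bins
    for c in range(classes - 1, 0, -1):
        i = cut[c][j]
        thresholds[c - 1] = edges[i]
        j = i
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("degenerate histogram: thresholds are not strictly increasing")
    return thresholds


def correct_hu_override(
    cbct: ScalarVolume,
    body: ROIMask,
    table: DensityClassTable | None = None,
    fov: ROIMask | None = None,
    bin_width: float = 1.0,
) -> CorrectedImage:
    """Multilevel-threshold density override of the CBCT.

    ``n_classes - 1`` thresholds are placed by multi-Otsu on the 1-HU-
    resolution grey-level histogram inside BODY (intersected with the FOV
    when given, so the outside-FOV air padding does not dominate the air
    class).  Every voxel of the grid is then assigned the density of its
    grey-level class; the raw CBCT values are retained unchanged alongside.
    Grey levels equal to a threshold fall in the lower class.
    """
    table = table or DensityClassTable()
    _require_same_grid(cbct, body)
    domain = intersect_masks(body, fov) if fov is not None else body
    grey = cbct.values[domain.values]
    if np.unique(grey).size < table.n_classes:
        raise ValueError(
            f"fewer than {table.n_classes} distinct grey levels inside the "
            "thresholding domain; use fewer classes"
        )
    thresholds = multiotsu_thresholds(grey, table.n_classes, bin_width)
    labels = np.searchsorted(thresholds, cbct.values, side="left")
    return CorrectedImage(
        method="CBCT_HU",
        hu=cbct.copy(),
        class_labels=labels,
        density_table=table,
        provenance={"thresholds": [float(t) for t in thresholds], "bin_width": bin_width},
    )


# ---------------------------------------------------------------------------
# Analytical correction and conversion


def estimate_conversion(
    cbct: ScalarVolume,
    ct_deformed: ScalarVolume,
    mask: ROIMask,
    n_bins: int = 128,
    support_fraction: float = 0.0001,
    min_support: int = 8,
    ridge: str = "median",
) -> ConversionFunction:
    """Estimate the grey-level conversion from a joint histogram of tissue pairs.

    A 2-D histogram of (CBCT grey, CT HU) pairs inside the mask is built over
    the central percentile range.  For each sufficiently populated CBCT
    column a ridge value is extracted — the conditional median of the CT HU
    (default; the L1-optimal estimate, robust to the mixing of tissues within
    a column) or the mean of the pairs in the modal CT bin (``ridge="mode"``).
    Anchors are monotonised with pool-adjacent-violators.
    """
    if ridge not in ("median", "mode"):
        raise ValueError("ridge must be 'median' or 'mode'")
    _require_same_grid(cbct, ct_deformed, mask)
    if not mask.values.any():
        raise ValueError("conversion mask is empty")
    g = cbct.values[mask.values]
    h = ct_deformed.values[mask.values]
    # keep the range wide enough to retain minority tissues (bone is well
    # under 1% of a breast FOV) while still clipping stray outliers
    g_lo, g_hi = np.percentile(g, [0.05, 99.95])
    h_lo, h_hi = np.percentile(h, [0.05, 99.95])
    if g_hi <= g_lo or h_hi <= h_lo:
        raise ValueError("degenerate intensity range for the joint histogram")
    g_edges = np.linspace(g_lo, g_hi, n_bins + 1)
    h_edges = np.linspace(h_lo, h_hi, n_bins + 1)
    hist, _, _ = np.histogram2d(g, h, bins=(g_edges, h_edges))
    support = max(support_fraction * g.size, float(min_support))

    g_bin = np.clip(np.digitize(g, g_edges) - 1, 0, n_bins - 1)
    h_bin = np.clip(np.digitize(h, h_edges) - 1, 0, n_bins - 1)
    anchors_in, anchors_out, weights = [], [], []
    for col in range(n_bins):
        count = hist[col].sum()
        if count < support:
            continue
        in_col = g_bin == col
        if ridge == "median":
            out = float(np.median(h[in_col]))
        else:
            modal = int(np.argmax(hist[col]))
            sel = in_col & (np.abs(h_bin - modal) <= 1)
            if not sel.any():
                continue
            out = float(np.mean(h[sel]))
        anchors_in.append(float(np.mean(g[in_col])))
        anchors_out.append(out)
        weights.append(float(count))
    if len(anchors_in) < 2:
        raise ValueError("fewer than 2 surviving joint-histogram columns")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    mono = iso.fit_transform(anchors_in, anchors_out, sample_weight=weights)
    return ConversionFunction(np.asarray(anchors_in), np.asarray(mono))


def _masked_lowpass(values: np.ndarray, mask: np.ndarray, sigma_vox: np.ndarray) -> np.ndarray:
    """Gaussian low-pass restricted to a mask (normalised so the FOV edge does not ring)."""
    m = mask.astype(float)
    num = ndimage.gaussian_filter(values * m, sigma_vox, mode="nearest")
    den = ndimage.gaussian_filter(m, sigma_vox, mode="nearest")
    out = np.zeros_like(values)
    good = den > 1e-6
    out[good] = num[good] / den[good]
    return out * mask


def correct_analytical(
    cbct: ScalarVolume,
    pct: ScalarVolume,
    fov: ROIMask,
    body: ROIMask | None = None,
    register=None,
    ground_truth_field: DeformationField | None = None,
    n_bins: int = 128,
    lp_fwhm_mm: float = 25.0,
    n_iter: int = 3,
) -> CorrectedImage:
    """Iterative analytical correction and conversion of the CBCT.

    Each iteration (1) deformably registers the reference CT to the current
    corrected CBCT (or uses the injected ground-truth field), (2) estimates
    and applies the grey-level conversion inside the FOV (air included, so
    the surrounding air anchors the low end of the map and contributes
    nothing to the difference map), and (3) adds a low-pass-filtered
    difference map (deformed CT minus current image, restricted to the FOV)
    to remove residual low-frequency shading.  The MAE against the deformed
    CT inside FOV ∩ BODY is tracked; the best iterate is kept and iteration
    stops early if it stops improving.  ``n_iter = 0`` returns the input
    unchanged.
    """
    _require_same_grid(cbct, pct, fov)
    current = cbct.copy()
    if n_iter == 0:
        return CorrectedImage(method="CBCT_CC", hu=current, provenance={"n_iter": 0})

    conv_mask = fov
    track_mask = intersect_masks(fov, body) if body is not None else fov
    sigma_vox = lp_fwhm_mm / 2.355 / np.asarray(cbct.grid.spacing)

    best = None
    best_mae = np.inf
    pct_def = None
    for it in range(n_iter):
        if ground_truth_field is not None:
            if pct_def is None:
                pct_def = warp_volume(pct, ground_truth_field)
        else:
            if register is None:
                from .registration import register_deformable as register  # noqa: PLW0127

            field_it = register(current, pct, conv_mask)
            pct_def = warp_volume(pct, field_it)

        conv = estimate_conversion(current, pct_def, conv_mask, n_bins=n_bins)
        converted = conv(current.values)
        diff = (pct_def.values - converted) * fov.values
        shading_corr = _masked_lowpass(diff, fov.values, sigma_vox)
        corrected = np.where(fov.values, converted + shading_corr, current.values)
        candidate = ScalarVolume(cbct.grid, corrected, "HU")
        mae_it = float(np.mean(np.abs(pct_def.values - corrected)[track_mask.values]))
        if mae_it < best_mae:
            best, best_mae = candidate, mae_it
            current = candidate
        else:  # stop once the masked MAE stops decreasing, keep the best iterate
            break
    return CorrectedImage(
        method="CBCT_CC",
        hu=best,
        provenance={"n_iter": n_iter, "lp_fwhm_mm": lp_fwhm_mm, "mae_vs_deformed_ct": best_mae},
    )


# ---------------------------------------------------------------------------
# Virtual CT


def detect_air_pockets(
    volume: ScalarVolume,
    body: ROIMask,
    hu_threshold: float = -300.0,
    min_volume_cc: float = 0.5,
    exclude: ROIMask | None = None,
) -> ROIMask:
    """Connected low-HU components inside the body larger than ``min_volume_cc``.

    Pockets are *internal* cavities: components connected to the exterior of
    the body (the skin partial-volume shell) do not count.  ``exclude`` names
    anatomy that is legitimately air-like (the lungs): any component touching
    it (within two voxels) is not a pocket either.
    """
    _require_same_grid(volume, body)
    candidate = (volume.values < hu_threshold) & body.values
    labels, n = ndimage.label(candidate)
    if n == 0:
        return ROIMask(volume.grid, np.zeros(volume.grid.shape, bool), "air_pockets")
    counts = np.bincount(labels.ravel())
    min_vox = min_volume_cc / volume.grid.voxel_volume_cc
    keep = np.flatnonzero(counts >= min_vox)
    keep = keep[keep > 0]
    if keep.size:
        exterior = ndimage.binary_dilation(~body.values)
        touch_ext = np.bincount(labels[exterior].ravel(), minlength=counts.size)
        keep = keep[touch_ext[keep] == 0]
    if exclude is not None and keep.size:
        touch = ndimage.binary_dilation(exclude.values, iterations=2)
        overlap = np.bincount(labels[touch].ravel(), minlength=counts.size)
        keep = keep[overlap[keep] == 0]
    out = np.isin(labels, keep)
    return ROIMask(volume.grid, out, "air_pockets")


def build_virtual_ct(
    pct: ScalarVolume,
    cbct_cc: CorrectedImage,
    field: DeformationField,
    body: ROIMask,
    hu_threshold: float = -300.0,
    min_volume_cc: float = 0.5,
    lungs: ROIMask | None = None,
    fov: ROIMask | None = None,
) -> CorrectedImage:
    """Deform the reference CT onto the CBCT, replacing air pockets from CBCT_CC.

    Air pockets detected in *either* the warped CT or the converted CBCT are
    replaced by CBCT_CC values; everywhere else the output equals the warped
    CT bit-exactly.  ``lungs`` (on the CBCT grid) is treated as legitimate
    low-density anatomy, never as a pocket; pocket detection on the converted
    CBCT is limited to ``fov`` when given (outside it the CBCT carries no
    information, only air padding).
    """
    if cbct_cc is None or cbct_cc.hu is None:
        raise ValueError("virtual CT requires the analytically corrected CBCT")
    warped = warp_volume(pct, field)
    cbct_domain = intersect_masks(body, fov) if fov is not None else body
    pockets_ct = detect_air_pockets(warped, body, hu_threshold, min_volume_cc, exclude=lungs)
    pockets_cbct = detect_air_pockets(
        cbct_cc.hu, cbct_domain, hu_threshold, min_volume_cc, exclude=lungs
    )
    replace = union_masks(pockets_ct, pockets_cbct).values
    values = warped.values.copy()
    values[replace] = cbct_cc.hu.values[replace]
    return CorrectedImage(
        method="CT_V",
        hu=ScalarVolume(warped.grid, values, "HU"),
        provenance={
            "replaced_voxels": int(replace.sum()),
            "hu_threshold": hu_threshold,
            "min_volume_cc": min_volume_cc,
        },
    )
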