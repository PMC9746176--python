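"""Synthetic thorax phantom: planning CT, deformed repeat CT and corrupted CBCT.

The generator emulates the study population this package targets: a breast
radiotherapy patient whose breast surface has deformed by more than 5 mm
between the planning CT (pCT) and a repeat CT (rCT), imaged in-room with a
CBCT whose Hounsfield scale is distorted, shaded by a smooth low-frequency
artifact field, noisy, and limited to a cylindrical field of view.  Every
corruption is returned as ground truth so correction accuracy downstream is
measurable exactly, and every operation is deterministic under its seed.

Anatomy is piecewise-constant HU: an elliptical thorax with a subcutaneous
adipose rim, two lungs, a heart, rib cross-sections and a hemispherical
breast with a glandular core.  Structures (BODY, whole-breast CTV, boost
CTV, heart, lungs) are emitted on both the pCT and rCT; CTVs are contracted
to stay at least 5 mm inside the BODY contour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .registration import warp_mask, warp_structures, warp_volume
from .volumes import (
    DeformationField,
    ImageGrid,
    ROIMask,
    ScalarVolume,
    StructureSet,
    erode_mask,
)

__all__ = [
    "PhantomParams",
    "DeformationSpec",
    "CBCTArtifactModel",
    "PhantomCase",
    "generate_phantom",
    "apply_breast_deformation",
    "simulate_cbct",
    "generate_case",
    "DEFAULT_TISSUE_HU",
]

# HU of each phantom tissue class (configurable through PhantomParams)
DEFAULT_TISSUE_HU = {
    "air": -1000.0,
    "lung": -750.0,
    "adipose": -90.0,
    "breast_glandular": 20.0,
    "soft_tissue": 40.0,
    "bone": 700.0,
}


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, tissue HU table, grid and noise of one synthetic patient."""

    shape: tuple[int, int, int] = (128, 128, 64)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    body_semi_axes: tuple[float, float] = (140.0, 88.0)  # mm, lateral / AP
    adipose_rim_mm: float = 12.0
    breast_lateral_offset: float = 55.0  # mm from midline
    breast_semi_axes: tuple[float, float, float] = (55.0, 45.0, 50.0)
    breast_skin_mm: float = 8.0  # adipose shell thickness of the breast
    laterality: str = "left"
    lung_semi_axes: tuple[float, float, float] = (45.0, 55.0, 65.0)
    lung_center_offset: tuple[float, float] = (62.0, 5.0)  # |x|, y of lung centers
    heart_radius: float = 38.0
    heart_center: tuple[float, float, float] = (18.0, 2.0, -12.0)
    rib_radius: float = 5.0
    n_ribs_per_side: int = 4
    boost_radius: float = 16.0
    tissue_hu: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_HU))
    ctv_skin_margin_mm: float = 5.0
    noise_sigma: float = 8.0  # HU, CT acquisition noise
    air_pocket_cc: float = 0.0  # optional air cavity in the upper mediastinum
    air_pocket_center: tuple[float, float, float] = (0.0, 30.0, 25.0)
    seed: int = 0

    @property
    def grid(self) -> ImageGrid:
        shape = np.asarray(self.shape)
        spacing = np.asarray(self.spacing)
        origin = -(shape - 1) * spacing / 2.0  # grid centered on the isocenter
        return ImageGrid(tuple(shape), tuple(spacing), tuple(origin))

    @property
    def side(self) -> float:
        if self.laterality not in ("left", "right"):
            raise ValueError(f"laterality must be 'left' or 'right', got {self.laterality!r}")
        return 1.0 if self.laterality == "left" else -1.0

    @property
    def breast_center(self) -> np.ndarray:
        """Center of the breast ellipsoid, on the anterior chest surface."""
        a, b = self.body_semi_axes
        x = self.side * self.breast_lateral_offset
        y = b * np.sqrt(max(1.0 - (x / a) ** 2, 0.0))
        return np.array([x, y, 0.0])


@dataclass(frozen=True)
class DeformationSpec:
    """Smooth breast-surface deformation between pCT and rCT anatomy."""

    mode: str = "swelling"  # or "shrinkage"
    peak_mm: float = 8.0  # peak surface displacement
    sigma_mm: float = 32.0  # Gaussian spatial scale of the surface bump
    support_mm: float = 96.0  # displacement is exactly zero beyond this radius

    def __post_init__(self) -> None:
        if self.mode not in ("swelling", "shrinkage"):
            raise ValueError(f"mode must be 'swelling' or 'shrinkage', got {self.mode!r}")
        if self.peak_mm < 0:
            raise ValueError("peak displacement must be >= 0")


@dataclass(frozen=True)
class CBCTArtifactModel:
    """Phenomenological CBCT corruption: HU-scale distortion + shading + noise + FOV.

    The grey-level distortion is ``g = gain * HU + offset + nl_amp * tanh(HU/1000)``
    and is strictly monotone over [-1000, 2000] HU for the defaults.  The
    shading field emulates scatter cupping: a systematic radial bowl across
    the FOV (depressed center, raised rim) mixed with a seeded in-plane
    Gaussian random field smoothed at ``shading_scale_mm`` (so the total
    field carries no energy above that spatial scale).  It is constant along
    the scanner axis and scaled to ``shading_amplitude`` peak HU inside the
    FOV; ``shading_cupping_fraction`` sets the systematic share.
    """

    gain: float = 0.9
    offset: float = -30.0  # HU
    nl_amp: float = 0.0  # optional mild nonlinearity
    shading_amplitude: float = 80.0  # HU, max |shading| inside the FOV
    shading_scale_mm: float = 100.0
    shading_cupping_fraction: float = 0.7  # systematic radial-bowl share
    noise_sigma: float = 20.0  # HU
    fov_radius: float = 130.0  # mm
    fov_length: float = 140.0  # mm along the scanner (z) axis
    fov_center: tuple[float, float] = (30.0, 30.0)  # in-plane axis position

    def __post_init__(self) -> None:
        if self.fov_radius <= 0:
            raise ValueError("FOV radius must be > 0")
        hu = np.linspace(-1000.0, 2000.0, 3001)
        if np.any(np.diff(self.distort(hu)) <= 0):
            raise ValueError("HU-scale distortion must be strictly monotone on [-1000, 2000]")

    def distort(self, hu: np.ndarray) -> np.ndarray:
        hu = np.asarray(hu, dtype=float)
        return self.gain * hu + self.offset + self.nl_amp * np.tanh(hu / 1000.0)

    def fov_axis(self, side: float = 1.0) -> np.ndarray:
        return np.array([side * abs(self.fov_center[0]), self.fov_center[1]])


@dataclass
class PhantomCase:
    """One complete synthetic study case with all ground truth attached."""

    pct: ScalarVolume
    rct: ScalarVolume
    cbct: ScalarVolume
    structures_pct: StructureSet
    structures_rct: StructureSet
    field: DeformationField  # ground truth, pulls rCT anatomy from pCT
    fov: ROIMask
    shading: ScalarVolume  # injected shading field (HU, zero outside FOV)
    artifact: CBCTArtifactModel
    params: PhantomParams
    deformation: DeformationSpec
    seed: int


# ---------------------------------------------------------------------------
# Anatomy


def _ellipsoid(X, Y, Z, center, semi) -> np.ndarray:
    return (
        ((X - center[0]) / semi[0]) ** 2
        + ((Y - center[1]) / semi[1]) ** 2
        + ((Z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _build_anatomy(params: PhantomParams) -> tuple[ScalarVolume, StructureSet]:
    """Noiseless piecewise-constant phantom and its structure set."""
    grid = params.grid
    X, Y, Z = grid.meshgrid()
    hu = params.tissue_hu
    a, b = params.body_semi_axes
    side = params.side

    thorax = ((X / a) ** 2 + (Y / b) ** 2) <= 1.0
    breast = _ellipsoid(X, Y, Z, params.breast_center, params.breast_semi_axes)
    body = thorax | breast

    values = np.full(grid.shape, hu["air"])
    values[body] = hu["soft_tissue"]

    # subcutaneous adipose rim of the thorax and outer shell of the breast
    dist_in = ndimage.distance_transform_edt(body, sampling=grid.spacing)
    rim = body & (dist_in <= params.adipose_rim_mm)
    values[rim] = hu["adipose"]

    # glandular breast core (inside the breast, below the skin/adipose shell)
    breast_core = breast & (dist_in > params.breast_skin_mm)
    values[breast_core] = hu["breast_glandular"]

    lungs = np.zeros(grid.shape, bool)
    for sx in (1.0, -1.0):
        cx = sx * params.lung_center_offset[0]
        lungs |= _ellipsoid(
            X, Y, Z, (cx, params.lung_center_offset[1], 0.0), params.lung_semi_axes
        )
    heart = _ellipsoid(
        X,
        Y,
        Z,
        (side * params.heart_center[0], params.heart_center[1], params.heart_center[2]),
        (params.heart_radius,) * 3,
    )
    for name, organ in (("lungs", lungs), ("heart", heart)):
        if np.any(organ & ~thorax):
            raise ValueError(f"phantom organ {name!r} exceeds the body bounds")
    values[lungs] = hu["lung"]
    values[heart] = hu["soft_tissue"]
    lungs &= ~heart

    # rib cross-sections: spheres on the thorax perimeter at several z levels
    ribs = np.zeros(grid.shape, bool)
    rib_angles = np.linspace(0.35 * np.pi, 1.65 * np.pi, 2 * params.n_ribs_per_side)
    z_levels = np.linspace(-50.0, 50.0, 4)
    for ang in rib_angles:
        cx = 0.88 * a * np.sin(ang)
        cy = 0.88 * b * np.cos(ang)
        for z0 in z_levels:
            ribs |= _ellipsoid(X, Y, Z, (cx, cy, z0), (params.rib_radius,) * 3)
    ribs &= thorax & ~lungs & ~heart
    values[ribs] = hu["bone"]

    if params.air_pocket_cc > 0:
        r = (3.0 * params.air_pocket_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        pocket = _ellipsoid(X, Y, Z, params.air_pocket_center, (r,) * 3)
        values[pocket & body] = hu["air"]

    body_mask = ROIMask(grid, body, "BODY")
    inner = erode_mask(body_mask, params.ctv_skin_margin_mm)
    ctv = ROIMask(grid, breast & inner.values, "whole_breast_CTV")
    boost_center = params.breast_center + np.array([0.0, -6.0, 0.0])
    boost = _ellipsoid(X, Y, Z, boost_center, (params.boost_radius,) * 3)
    boost_mask = ROIMask(grid, boost & ctv.values, "boost_CTV")

    for name, m in (("lungs", lungs), ("heart", heart), ("boost", boost_mask.values)):
        if np.any(m & ~body):
            raise ValueError(f"phantom organ {name!r} exceeds the body bounds")
    if ctv.n_voxels == 0 or boost_mask.n_voxels == 0:
        raise ValueError("CTV construction produced an empty mask; check geometry")

    structures = StructureSet(
        {
            "BODY": body_mask,
            "whole_breast_CTV": ctv,
            "boost_CTV": boost_mask,
            "heart": ROIMask(grid, heart, "heart"),
            "lungs": ROIMask(grid, lungs, "lungs"),
        },
        external="BODY",
    )
    return ScalarVolume(grid, values, "HU"), structures


def generate_phantom(
    params: PhantomParams, rng: np.random.Generator | None = None
) -> tuple[ScalarVolume, StructureSet]:
    """Generate the planning CT and its structures, deterministic given the seed."""
    pct, structures = _build_anatomy(params)
    if params.noise_sigma > 0:
        rng = rng if rng is not None else np.random.default_rng(params.seed)
        pct = pct.with_values(
            pct.values + rng.normal(0.0, params.noise_sigma, pct.grid.shape)
        )
    return pct, structures


# ---------------------------------------------------------------------------
# Deformation


def _bump_weight(pts: np.ndarray, anchor: np.ndarray, spec: DeformationSpec) -> np.ndarray:
    """Gaussian bump of distance to the surface anchor, with compact support."""
    r = np.linalg.norm(pts - anchor, axis=-1)
    w = np.exp(-(r**2) / (2.0 * spec.sigma_mm**2))
    # C1 fade to exactly zero at the support edge
    edge = np.clip((spec.support_mm - r) / (0.25 * spec.support_mm), 0.0, 1.0)
    return w * edge * edge * (3.0 - 2.0 * edge)


def build_deformation_field(
    grid: ImageGrid, params: PhantomParams, spec: DeformationSpec
) -> DeformationField:
    """Ground-truth pull-back displacement realising the requested surface motion."""
    if spec.peak_mm == 0:
        return DeformationField.identity(grid)
    center = params.breast_center
    by = params.breast_semi_axes[1]
    anchor = center + np.array([0.0, by, 0.0])  # breast apex, on the surface
    X, Y, Z = grid.meshgrid()
    pts = np.stack([X, Y, Z], axis=-1)
    w = _bump_weight(pts, anchor, spec)
    d = pts - center
    norm = np.linalg.norm(d, axis=-1)
    dhat = np.where(norm[..., None] > 1e-9, d / np.maximum(norm, 1e-9)[..., None], 0.0)
    # taper the radial direction near the breast center so the field stays C1
    # (the radial unit vector itself is discontinuous there)
    t = np.clip(norm / 30.0, 0.0, 1.0)
    taper = t * t * (3.0 - 2.0 * t)
    sign = -1.0 if spec.mode == "swelling" else 1.0
    field = DeformationField(
        grid, sign * spec.peak_mm * (w * taper)[..., None] * dhat
    )
    if np.any(field.jacobian_determinant() <= 0):
        raise ValueError(
            "deformation field folds (non-positive Jacobian); reduce peak or widen sigma"
        )
    return field


def apply_breast_deformation(
    pct: ScalarVolume,
    structures: StructureSet,
    spec: DeformationSpec,
    params: PhantomParams | None = None,
) -> tuple[ScalarVolume, StructureSet, DeformationField]:
    """Warp the pCT anatomy into the rCT anatomy with a known smooth field."""
    params = params or PhantomParams()
    field = build_deformation_field(pct.grid, params, spec)
    if spec.peak_mm == 0:
        return pct.copy(), structures, field
    rct = warp_volume(pct, field)
    structures_rct = warp_structures(structures, field)
    return rct, structures_rct, field


def forward_displacement(field: DeformationField, points: np.ndarray, n_iter: int = 30) -> np.ndarray:
    """Forward motion of material points under a pull-back field.

    Solves y + u(y) = x by fixed-point iteration; returns y - x.  Used as the
    surface-tracking oracle for the deformation's peak displacement.
    """
    pts = np.asarray(points, dtype=float)
    y = pts.copy()
    for _ in range(n_iter):
        idx = field.grid.world_to_index(y)
        coords = np.moveaxis(idx, -1, 0)
        u = np.stack(
            [
                ndimage.map_coordinates(
                    field.displacement[..., c], coords, order=1, mode="nearest"
                )
                for c in range(3)
            ],
            axis=-1,
        )
        y = pts - u
    return y - pts


# ---------------------------------------------------------------------------
# CBCT simulation


def fov_cylinder_mask(
    grid: ImageGrid, artifact: CBCTArtifactModel, side: float = 1.0
) -> ROIMask:
    X, Y, Z = grid.meshgrid()
    cx, cy = artifact.fov_axis(side)
    inside = ((X - cx) ** 2 + (Y - cy) ** 2 <= artifact.fov_radius**2) & (
        np.abs(Z) <= artifact.fov_length / 2.0
    )
    return ROIMask(grid, inside, "FOV")


def _shading_field(
    grid: ImageGrid,
    artifact: CBCTArtifactModel,
    rng: np.random.Generator,
    fov_inplane: np.ndarray | None = None,
    side: float = 1.0,
) -> np.ndarray:
    """Seeded in-plane Gaussian random field, band-limited at the shading scale.

    The field is scaled so its peak magnitude *inside the FOV* equals the
    configured amplitude (the corrupted region is what the amplitude
    describes; outside the FOV the CBCT is air-filled anyway).
    """
    if artifact.shading_amplitude == 0:
        return np.zeros(grid.shape)
    nx, ny = grid.shape[0], grid.shape[1]
    region = fov_inplane if fov_inplane is not None else np.ones((nx, ny), bool)

    # systematic scatter cupping: radial bowl over the FOV, range [-1, 1]
    ax = grid.axes()
    cx, cy = artifact.fov_axis(side)
    X, Y = np.meshgrid(ax[0], ax[1], indexing="ij")
    r2 = ((X - cx) ** 2 + (Y - cy) ** 2) / artifact.fov_radius**2
    bowl = 2.0 * np.clip(r2, 0.0, 1.0) - 1.0

    # patient/seed-dependent low-frequency component
    white = rng.standard_normal((nx, ny))
    sigma_vox = (
        artifact.shading_scale_mm / 2.355 / np.asarray(grid.spacing[:2])
    )  # FWHM -> sigma
    smooth = ndimage.gaussian_filter(white, sigma_vox, mode="nearest")
    rnd_peak = np.max(np.abs(smooth[region])) if region.any() else 0.0
    rnd = smooth / rnd_peak if rnd_peak > 1e-12 else np.zeros_like(smooth)

    f = artifact.shading_cupping_fraction
    plane = f * bowl + (1.0 - f) * rnd
    peak = np.max(np.abs(plane[region])) if region.any() else 0.0
    if peak < 1e-12:
        return np.zeros(grid.shape)
    plane = plane * (artifact.shading_amplitude / peak)
    return np.repeat(plane[:, :, None], grid.shape[2], axis=2)


def simulate_cbct(
    rct: ScalarVolume,
    artifact: CBCTArtifactModel,
    seed: int = 0,
    side: float = 1.0,
) -> tuple[ScalarVolume, ROIMask, ScalarVolume]:
    """Corrupt the rCT into a CBCT: distortion + shading + noise inside a cylindrical FOV.

    Returns (CBCT, FOV mask, injected shading field); outside the FOV the
    CBCT is filled with air (-1000 HU).
    """
    rng = np.random.default_rng(seed)
    fov = fov_cylinder_mask(rct.grid, artifact, side)
    if not fov.values.any():
        raise ValueError("CBCT FOV cylinder does not intersect the image grid")
    shading = _shading_field(rct.grid, artifact, rng, fov.values.any(axis=2), side)
    values = artifact.distort(rct.values) + shading
    if artifact.noise_sigma > 0:
        values = values + rng.normal(0.0, artifact.noise_sigma, rct.grid.shape)
    values = np.where(fov.values, values, -1000.0)
    shading_vol = ScalarVolume(rct.grid, np.where(fov.values, shading, 0.0), "HU")
    return ScalarVolume(rct.grid, values, "HU"), fov, shading_vol


# ---------------------------------------------------------------------------
# Full case


def generate_case(
    params: PhantomParams | None = None,
    deformation: DeformationSpec | None = None,
    artifact: CBCTArtifactModel | None = None,
    seed: int = 0,
) -> PhantomCase:
    """Generate a full pCT / rCT / CBCT study case, deterministic under ``seed``.

    The pCT and rCT carry independent CT noise realisations on the same
    underlying (deformed) anatomy; the CBCT corrupts the noisy rCT.
    """
    params = replace(params or PhantomParams(), seed=seed)
    deformation = deformation or DeformationSpec()
    artifact = artifact or CBCTArtifactModel()
    rng = np.random.default_rng(seed)
    s_pct, s_rct, s_cbct = (int(x) for x in rng.integers(0, 2**31 - 1, 3))

    anatomy, structures = _build_anatomy(params)
    rct_anatomy, structures_rct, gt_field = apply_breast_deformation(
        anatomy, structures, deformation, params
    )
    noise = np.random.default_rng(s_pct)
    pct = anatomy.with_values(
        anatomy.values + noise.normal(0.0, params.noise_sigma, anatomy.grid.shape)
        if params.noise_sigma > 0
        else anatomy.values
    )
    noise = np.random.default_rng(s_rct)
    rct = rct_anatomy.with_values(
        rct_anatomy.values + noise.normal(0.0, params.noise_sigma, anatomy.grid.shape)
        if params.noise_sigma > 0
        else rct_anatomy.values
    )
    cbct, fov, shading = simulate_cbct(rct, artifact, seed=s_cbct, side=params.side)
    return PhantomCase(
        pct=pct,
        rct=rct,
        cbct=cbct,
        structures_pct=structures,
        structures_rct=structures_rct,
        field=gt_field,
        fov=fov,
        shading=shading,
        artifact=artifact,
        params=params,
        deformation=deformation,
        seed=seed,
    )
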