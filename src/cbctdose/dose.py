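"""Surrogate dose engine for the partial-VMAT breast plan, plus DVH statistics.

The engine models primary photon fluence only: per beam control point the
dose at a point is

    weight * T(u, v) * exp(-mu_eff * r) * (SAD / t)^2

where ``T`` is a divergent rectangular aperture with a smooth (but compactly
supported) penumbra, ``r`` the radiological path from the source in
water-equivalent cm, ``t`` the source distance and ``SAD`` the source-axis
distance.  There is no scatter kernel: the package's dose conclusions are
relative comparisons between image sets under this one engine.  Radiological
depth for the volume is computed per control point on a divergent
beam's-eye-view lattice (cumulative sum along each ray) and interpolated to
the voxels; the exact Siddon voxel traversal is available as
:func:`radiological_path` and serves as the engine's path-length oracle.

The plan layout mirrors a 70%/30% conformal-plus-VMAT breast technique: two
opposed tangential rectangular fields carry 70% of the weight and four short
arcs (40-80 degrees each) the remaining 30%.  A plan is normalised once so
the mean whole-breast-CTV dose on the planning CT equals the prescription,
and that scale is frozen and reused on every other image set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import ImageGrid, ROIMask, ScalarVolume, _require_same_grid

__all__ = [
    "HUDensityTable",
    "ControlPoint",
    "TreatmentPlan",
    "DVHStatistics",
    "hu_to_density",
    "override_outside_fov",
    "build_partial_vmat_plan",
    "normalize_plan",
    "compute_dose",
    "radiological_path",
    "dvh_stats",
    "dose_difference_report",
]


@dataclass(frozen=True)
class HUDensityTable:
    """Monotone piecewise-linear HU -> mass density (g/cm^3) conversion."""

    anchors_hu: tuple[float, ...] = (-1000.0, 0.0, 1000.0, 3000.0)
    anchors_density: tuple[float, ...] = (0.00121, 1.0, 1.6, 3.0)

    def __post_init__(self) -> None:
        if len(self.anchors_hu) != len(self.anchors_density):
            raise ValueError("anchor lists must have equal length")
        if np.any(np.diff(self.anchors_hu) <= 0):
            raise ValueError("HU anchors must be strictly increasing")
        if np.any(np.diff(self.anchors_density) < 0) or min(self.anchors_density) < 0:
            raise ValueError("density anchors must be non-negative and non-decreasing")

    def __call__(self, hu: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(hu, dtype=float), self.anchors_hu, self.anchors_density)


def hu_to_density(volume: ScalarVolume, table: HUDensityTable | None = None) -> ScalarVolume:
    """Voxelwise piecewise-linear HU -> density map, clamped at the anchor ends."""
    table = table or HUDensityTable()
    return ScalarVolume(volume.grid, table(volume.values), "density")


def override_outside_fov(
    density: ScalarVolume,
    body: ROIMask,
    fov: ROIMask,
    value: float = 1.0,
) -> ScalarVolume:
    """Set density to ``value`` (g/cm^3) inside BODY but outside the CBCT FOV."""
    _require_same_grid(density, body, fov)
    out = density.values.copy()
    out[body.values & ~fov.values] = value
    return ScalarVolume(density.grid, out, "density")


# ---------------------------------------------------------------------------
# Plan geometry


@dataclass(frozen=True)
class ControlPoint:
    """One static beam or arc control point: gantry angle, weight, BEV aperture."""

    gantry_deg: float
    weight: float
    aperture: tuple[float, float, float, float]  # (u_min, u_max, v_min, v_max) mm at iso


@dataclass
class TreatmentPlan:
    prescription: float  # Gy
    isocenter: tuple[float, float, float]
    control_points: list[ControlPoint]
    sad: float = 1000.0  # mm
    mu_eff: float = 0.05  # 1/cm, effective attenuation (~6 MV)
    penumbra_mm: float = 4.0
    scale: float | None = None  # monitor-unit analogue, set once by normalize_plan
    fractionation: str = "16Fx2.66"

    def __post_init__(self) -> None:
        if self.prescription <= 0:
            raise ValueError("prescription must be > 0")
        w = sum(cp.weight for cp in self.control_points)
        if abs(w - 1.0) > 1e-6:
            raise ValueError(f"control point weights must sum to 1, got {w}")


def _source_position(iso: np.ndarray, gantry_deg: float, sad: float) -> np.ndarray:
    g = np.deg2rad(gantry_deg)
    return iso + sad * np.array([np.sin(g), np.cos(g), 0.0])


def _beam_frame(iso: np.ndarray, gantry_deg: float, sad: float):
    src = _source_position(iso, gantry_deg, sad)
    e3 = (iso - src) / sad
    e1 = np.cross([0.0, 0.0, 1.0], e3)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(e3, e1)
    return src, e1, e2, e3


def _project_bev(points: np.ndarray, src, e1, e2, e3, sad: float):
    """Project world points to the isocenter-plane BEV; returns (u, v, depth)."""
    d = points - src
    depth = d @ e3
    u = (d @ e1) / depth * sad
    v = (d @ e2) / depth * sad
    return u, v, depth


def _fit_aperture(ctv_points: np.ndarray, iso, gantry_deg, sad, margin_mm):
    src, e1, e2, e3 = _beam_frame(iso, gantry_deg, sad)
    u, v, depth = _project_bev(ctv_points, src, e1, e2, e3, sad)
    if np.any(depth <= 0):
        raise ValueError("CTV lies behind the source for this gantry angle")
    return (
        float(u.min() - margin_mm),
        float(u.max() + margin_mm),
        float(v.min() - margin_mm),
        float(v.max() + margin_mm),
    )


_LEFT_ARCS = ((20.0, 70.0), (70.0, 120.0), (90.0, 140.0), (100.0, 150.0))
_TANGENTIAL_OFFSET_DEG = 72.0  # from the target's anterior bearing to the grazing axis


def build_partial_vmat_plan(
    ctv: ROIMask,
    prescription: float = 42.56,
    laterality: str = "left",
    conformal_weight: float = 0.70,
    arc_weight: float = 0.30,
    cp_spacing_deg: float = 5.0,
    aperture_margin_mm: float = 7.0,
    sad: float = 1000.0,
    mu_eff: float = 0.05,
    fractionation: str = "16Fx2.66",
) -> TreatmentPlan:
    """Build the 70% tangential / 30% short-arc surrogate breast plan.

    Apertures are auto-fitted to the CTV's BEV projection plus a margin at
    every control point (conformal-arc approximation of the VMAT arcs); the
    isocenter is the CTV centroid.  The two opposed tangential axes are
    derived from the target geometry: they graze the chest wall, offset from
    the breast's anterior bearing so the fields exit without crossing the
    mediastinum.
    """
    if abs(conformal_weight + arc_weight - 1.0) > 1e-9:
        raise ValueError("conformal and arc weights must sum to 1")
    if ctv.n_voxels == 0:
        raise ValueError("CTV mask is empty")
    X, Y, Z = ctv.grid.meshgrid()
    pts = np.stack([X[ctv.values], Y[ctv.values], Z[ctv.values]], axis=-1)
    iso = pts.mean(axis=0)

    mirror = 1.0 if laterality == "left" else -1.0

    def ang(a: float) -> float:
        return a if mirror > 0 else (360.0 - a) % 360.0

    bearing = float(np.rad2deg(np.arctan2(iso[0], iso[1])))  # anterior = 0 deg
    tangentials = (
        (bearing + mirror * _TANGENTIAL_OFFSET_DEG) % 360.0,
        (bearing + mirror * _TANGENTIAL_OFFSET_DEG + 180.0) % 360.0,
    )
    cps: list[ControlPoint] = []
    for g in tangentials:
        cps.append(
            ControlPoint(
                g,
                conformal_weight / len(tangentials),
                _fit_aperture(pts, iso, g, sad, aperture_margin_mm),
            )
        )
    per_arc = arc_weight / len(_LEFT_ARCS)
    for start, stop in _LEFT_ARCS:
        span = abs(stop - start)
        if not (40.0 <= span <= 80.0):
            raise ValueError(f"arc span {span} deg outside the 40-80 deg range")
        n_cp = max(int(round(span / cp_spacing_deg)) + 1, 2)
        angles = np.linspace(start, stop, n_cp)
        for g in angles:
            cps.append(
                ControlPoint(
                    ang(float(g)),
                    per_arc / n_cp,
                    _fit_aperture(pts, iso, ang(float(g)), sad, aperture_margin_mm),
                )
            )
    total = sum(cp.weight for cp in cps)
    cps = [replace(cp, weight=cp.weight / total) for cp in cps]
    return TreatmentPlan(
        prescription=prescription,
        isocenter=tuple(iso),
        control_points=cps,
        sad=sad,
        mu_eff=mu_eff,
        fractionation=fractionation,
    )


# ---------------------------------------------------------------------------
# Ray tracing


def radiological_path(density: ScalarVolume, p0, p1) -> float:
    """Exact water-equivalent path length (cm) along the segment p0 -> p1.

    Siddon-style voxel traversal: the segment is cut at every voxel boundary
    plane and each piece contributes its length times the density of the
    voxel it crosses.  Points outside the grid contribute nothing (vacuum).
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    length = np.linalg.norm(d)
    if length < 1e-12:
        return 0.0
    grid = density.grid
    alphas = [0.0, 1.0]
    for ax in range(3):
        if abs(d[ax]) < 1e-12:
            continue
        # voxel boundary planes sit half a spacing beyond each voxel center
        bounds = grid.origin[ax] + (np.arange(grid.shape[ax] + 1) - 0.5) * grid.spacing[ax]
        a = (bounds - p0[ax]) / d[ax]
        alphas.extend(a[(a > 0.0) & (a < 1.0)].tolist())
    alphas = np.unique(np.asarray(alphas))
    mids = p0[None, :] + 0.5 * (alphas[:-1] + alphas[1:])[:, None] * d[None, :]
    seg_len = np.diff(alphas) * length
    idx = np.floor(grid.world_to_index(mids) + 0.5).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    if not inside.any():
        return 0.0
    rho = density.values[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
    return float(np.sum(rho * seg_len[inside]) / 10.0)  # mm -> cm


def _smoothstep(x: np.ndarray) -> np.ndarray:
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _aperture_transmission(u, v, aperture, penumbra_mm):
    u_min, u_max, v_min, v_max = aperture
    inside = np.minimum.reduce([u - u_min, u_max - u, v - v_min, v_max - v])
    # smooth penumbra, exactly zero beyond one penumbra width outside the edge
    return _smoothstep((inside + penumbra_mm) / (2.0 * penumbra_mm))


def _depth_lattice(density, src, e1, e2, e3, sad, aperture, penumbra_mm, step_mm):
    """Radiological depth (cm) on a divergent BEV lattice, cumulative along rays."""
    u_min, u_max, v_min, v_max = aperture
    pad = penumbra_mm + 6.0
    nu = max(int(np.ceil((u_max - u_min + 2 * pad) / step_mm)) + 1, 2)
    nv = max(int(np.ceil((v_max - v_min + 2 * pad) / step_mm)) + 1, 2)
    us = np.linspace(u_min - pad, u_max + pad, nu)
    vs = np.linspace(v_min - pad, v_max + pad, nv)

    lo, hi = density.grid.extent()
    corners = np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    dist = np.linalg.norm(corners - src, axis=1)
    s0, s1 = max(float(dist.min()) - 10.0, 1.0), float(dist.max()) + 10.0
    ns = max(int(np.ceil((s1 - s0) / step_mm)) + 1, 2)
    ss = np.linspace(s0, s1, ns)
    ds = ss[1] - ss[0]

    U, V = np.meshgrid(us, vs, indexing="ij")
    dirs = e3[None, None, :] + (U / sad)[..., None] * e1[None, None, :] + (V / sad)[..., None] * e2[None, None, :]
    dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
    pts = src[None, None, None, :] + ss[None, None, :, None] * dirs[:, :, None, :]
    coords = np.moveaxis(density.grid.world_to_index(pts), -1, 0)
    rho = ndimage.map_coordinates(density.values, coords, order=1, mode="constant", cval=0.0)
    # midpoint cumulative sum: depth at sample k integrates density up to s_k
    depth = np.cumsum(0.5 * (rho + np.roll(rho, 1, axis=2)), axis=2) * ds / 10.0
    depth[:, :, 0] = 0.0
    return us, vs, ss, depth


def compute_dose(
    density: ScalarVolume,
    plan: TreatmentPlan,
    bev_step_mm: float = 3.0,
) -> ScalarVolume:
    """Dose (Gy) of the frozen plan on a density volume.

    Requires ``plan.scale`` to be set (see :func:`normalize_plan`); an
    unnormalised plan computes in arbitrary units with scale 1.
    """
    grid = density.grid
    iso = np.asarray(plan.isocenter)
    X, Y, Z = grid.meshgrid()
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
    dose = np.zeros(pts.shape[0])
    scale = plan.scale if plan.scale is not None else 1.0

    for cp in plan.control_points:
        src, e1, e2, e3 = _beam_frame(iso, cp.gantry_deg, plan.sad)
        u, v, depth_pt = _project_bev(pts, src, e1, e2, e3, plan.sad)
        T = _aperture_transmission(u, v, cp.aperture, plan.penumbra_mm)
        sel = (T > 0.0) & (depth_pt > 0.0)
        if not sel.any():
            continue
        us, vs, ss, depth = _depth_lattice(
            density, src, e1, e2, e3, plan.sad, cp.aperture, plan.penumbra_mm, bev_step_mm
        )
        t = np.linalg.norm(pts[sel] - src, axis=1)
        ci = np.stack(
            [
                np.interp(u[sel], us, np.arange(us.size)),
                np.interp(v[sel], vs, np.arange(vs.size)),
                np.interp(t, ss, np.arange(ss.size)),
            ]
        )
        r = ndimage.map_coordinates(depth, ci, order=1, mode="nearest")
        dose[np.flatnonzero(sel)] += (
            cp.weight * T[sel] * np.exp(-plan.mu_eff * r) * (plan.sad / t) ** 2
        )
    return ScalarVolume(grid, scale * dose.reshape(grid.shape), "dose")


def normalize_plan(
    plan: TreatmentPlan, density: ScalarVolume, ctv: ROIMask, bev_step_mm: float = 3.0
) -> TreatmentPlan:
    """Set the plan's frozen output scale so the mean CTV dose equals the prescription.

    Called exactly once, with the planning-CT density; the same scale is then
    reused unchanged on every other image set.
    """
    if ctv.n_voxels == 0:
        raise ValueError("normalisation CTV is empty")
    raw = compute_dose(density, replace(plan, scale=1.0), bev_step_mm)
    mean_ctv = float(raw.values[ctv.values].mean())
    if mean_ctv <= 0:
        raise ValueError("CTV receives no dose; it lies outside all beams")
    out = replace(plan, scale=plan.prescription / mean_ctv)
    return out


# ---------------------------------------------------------------------------
# DVH statistics


@dataclass(frozen=True)
class DVHStatistics:
    """D1/D2/D95/D98/D99 and mean dose for one ROI, absolute and relative."""

    roi: str
    prescription: float
    d1: float
    d2: float
    d95: float
    d98: float
    d99: float
    mean: float

    def __post_init__(self) -> None:
        if not (self.d99 <= self.d98 + 1e-9 and self.d98 <= self.d95 + 1e-9):
            raise ValueError("DVH ordering violated: need D99 <= D98 <= D95")
        if self.d1 + 1e-9 < self.d2:
            raise ValueError("DVH ordering violated: need D2 <= D1")

    def as_dict(self, relative: bool = False) -> dict[str, float]:
        d = {
            "D1": self.d1,
            "D2": self.d2,
            "D95": self.d95,
            "D98": self.d98,
            "D99": self.d99,
            "mean": self.mean,
        }
        if relative:
            return {k: 100.0 * v / self.prescription for k, v in d.items()}
        return d


def dvh_stats(dose: ScalarVolume, roi: ROIMask, prescription: float) -> DVHStatistics:
    """Dx = dose received by at least x% of the ROI volume (top-down percentile).

    Computed as the (100 - x)-th percentile of the voxel doses with linear
    interpolation between order statistics; the mean is arithmetic.
    """
    _require_same_grid(dose, roi)
    if roi.n_voxels == 0:
        raise ValueError("DVH ROI is empty")
    d = dose.values[roi.values]
    q = np.percentile(d, [99.0, 98.0, 5.0, 2.0, 1.0], method="linear")
    return DVHStatistics(
        roi=roi.name,
        prescription=prescription,
        d1=float(q[0]),
        d2=float(q[1]),
        d95=float(q[2]),
        d98=float(q[3]),
        d99=float(q[4]),
        mean=float(d.mean()),
    )


def dose_difference_report(
    reference: DVHStatistics, others: dict[str, DVHStatistics]
) -> pd.DataFrame:
    """Per image set and statistic: (value - reference) / prescription * 100 (%)."""
    rows = []
    ref = reference.as_dict()
    for name, stats in others.items():
        if abs(stats.prescription - reference.prescription) > 1e-9:
            raise ValueError(f"prescription mismatch for image set {name!r}")
        row = {"image_set": name}
        for k, v in stats.as_dict().items():
            row[k] = 100.0 * (v - ref[k]) / reference.prescription
        rows.append(row)
    return pd.DataFrame(rows).set_index("image_set")
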