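"""Core data model: image grids, scalar volumes, ROI masks, transforms, and I/O.

All geometry lives in a single right-handed patient coordinate convention:
world coordinates are millimetres, voxel indices address voxel centers, and
the world position of voxel ``(i, j, k)`` is ``origin + index * spacing``.
Arrays are indexed ``[ix, iy, iz]`` (x first); converters to and from
SimpleITK handle the axis transposition.  Masks are defined at voxel centers:
a voxel belongs to an ROI iff its center lies inside the region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "ImageGrid",
    "ScalarVolume",
    "ROIMask",
    "StructureSet",
    "RigidTransform",
    "DeformationField",
    "GridMismatchError",
    "VolumeIOError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_structure_set",
    "write_structure_set",
    "read_deformation_field",
    "write_deformation_field",
    "resample_to_grid",
    "resample_mask_to_grid",
    "erode_mask",
    "intersect_masks",
    "union_masks",
    "subtract_masks",
]


class GridMismatchError(ValueError):
    """Two objects that must share a grid do not; resample one first."""


class VolumeIOError(IOError):
    """A volume file could not be read or its header is inconsistent."""


# Default out-of-extent fill values per physical quantity.
_DEFAULT_FILL = {"HU": -1000.0, "density": 0.0, "dose": 0.0, "gamma": 0.0}


@dataclass(frozen=True)
class ImageGrid:
    """A regular 3-D voxel lattice: shape (voxels), spacing and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("ImageGrid is strictly 3-D")
        if any(n < 1 for n in self.shape):
            raise ValueError(f"grid shape must be >= 1 on all axes, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be > 0 on all axes, got {self.spacing}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3."""
        return float(np.prod(self.spacing)) / 1000.0

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (mm) of voxel centers along each axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinate arrays X, Y, Z of every voxel center, shape = grid shape."""
        ax = self.axes()
        return np.meshgrid(ax[0], ax[1], ax[2], indexing="ij")

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) world coordinates of the voxel-center bounding box."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world points (mm), shape (..., 3)."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def same_as(self, other: "ImageGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def _require_same_grid(*objs) -> None:
    g0 = objs[0].grid
    for o in objs[1:]:
        if not g0.same_as(o.grid):
            raise GridMismatchError(
                "objects are on different grids; resample to a common grid first "
                f"({g0} vs {o.grid})"
            )


@dataclass
class ScalarVolume:
    """One scalar per voxel on an :class:`ImageGrid` plus a quantity tag.

    ``quantity`` is one of ``HU``, ``density`` (g/cm^3), ``dose`` (Gy),
    ``gamma``; it selects the physically neutral fill value used when the
    volume is resampled beyond its extent.
    """

    grid: ImageGrid
    values: np.ndarray
    quantity: str = "HU"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")
        if self.quantity in ("density", "dose") and np.any(self.values < 0):
            raise ValueError(f"{self.quantity} values must be non-negative")

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid, self.values.copy(), self.quantity)

    def with_values(self, values: np.ndarray) -> "ScalarVolume":
        return ScalarVolume(self.grid, values, self.quantity)


@dataclass
class ROIMask:
    """Boolean membership volume for one region of interest."""

    grid: ImageGrid
    values: np.ndarray
    name: str = "ROI"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cc(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_cc

    def copy(self, name: str | None = None) -> "ROIMask":
        return ROIMask(self.grid, self.values.copy(), name or self.name)


@dataclass
class StructureSet:
    """Named ROI masks on one shared grid, with exactly one flagged External/BODY."""

    masks: dict[str, ROIMask]
    external: str = "BODY"

    def __post_init__(self) -> None:
        if self.external not in self.masks:
            raise ValueError(f"external structure {self.external!r} not in set")
        grids = list(self.masks.values())
        _require_same_grid(*grids)

    @property
    def grid(self) -> ImageGrid:
        return next(iter(self.masks.values())).grid

    @property
    def body(self) -> ROIMask:
        return self.masks[self.external]

    def __getitem__(self, name: str) -> ROIMask:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    def clip_to_body(self) -> "StructureSet":
        """Intersect every non-External mask with the BODY contour."""
        body = self.body
        out = {}
        for name, m in self.masks.items():
            if name == self.external:
                out[name] = m.copy()
            else:
                out[name] = ROIMask(m.grid, m.values & body.values, name)
        return StructureSet(out, self.external)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid transform: rotation (degrees, about x/y/z) then translation (mm).

    Maps a point p to ``R (p - center) + center + translation`` with R built
    from the three Euler angles applied in x, y, z order.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        from scipy.spatial.transform import Rotation

        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        c = np.asarray(self.center)
        t = np.asarray(self.translation_mm)
        return (pts - c) @ self.matrix().T + c + t

    def inverse(self) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        R = self.matrix()
        rot_inv = Rotation.from_matrix(R.T).as_euler("xyz", degrees=True)
        c = np.asarray(self.center)
        t = np.asarray(self.translation_mm)
        # inverse of p -> R(p-c)+c+t is p -> R^T(p-c)+c - R^T t
        return RigidTransform(
            tuple(rot_inv), tuple(-R.T @ t), tuple(c)
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "rotation_deg": list(self.rotation_deg),
                "translation_mm": list(self.translation_mm),
                "center": list(self.center),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        d = json.loads(text)
        return cls(
            tuple(d["rotation_deg"]), tuple(d["translation_mm"]), tuple(d["center"])
        )


@dataclass
class DeformationField:
    """Per-voxel 3-vector displacement (mm) on a grid, pull-back convention.

    ``warp(volume, field)`` samples the moving volume at ``x + u(x)`` for each
    voxel center x of the field's grid; the all-zero field is the identity.
    """

    grid: ImageGrid
    displacement: np.ndarray  # shape grid.shape + (3,)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.shape != self.grid.shape + (3,):
            raise ValueError(
                f"displacement shape {self.displacement.shape} != {self.grid.shape + (3,)}"
            )
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement components must be finite")

    @classmethod
    def identity(cls, grid: ImageGrid) -> "DeformationField":
        return cls(grid, np.zeros(grid.shape + (3,)))

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.displacement, axis=-1)

    def jacobian_determinant(self) -> np.ndarray:
        """Determinant of the Jacobian of the map x -> x + u(x) (finite differences)."""
        J = np.empty(self.grid.shape + (3, 3))
        for comp in range(3):
            for ax in range(3):
                J[..., comp, ax] = np.gradient(
                    self.displacement[..., comp], self.grid.spacing[ax], axis=ax
                )
            J[..., comp, comp] += 1.0
        return np.linalg.det(J)


# ---------------------------------------------------------------------------
# I/O via SimpleITK (NIfTI and NRRD)


def _to_sitk(values: np.ndarray, grid: ImageGrid, dtype=None) -> sitk.Image:
    arr = values.transpose(2, 1, 0)  # (x,y,z) -> sitk's (z,y,x) array layout
    if dtype is not None:
        arr = arr.astype(dtype)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, ImageGrid]:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        # readers reorient on load so all internal volumes share one convention
        img = sitk.DICOMOrient(img, "LPS")
        direction = np.asarray(img.GetDirection()).reshape(3, 3)
        if not np.allclose(direction, np.eye(3), atol=1e-6):
            raise VolumeIOError(
                f"cannot reorient oblique image (direction {direction.tolist()})"
            )
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    grid = ImageGrid(arr.shape, img.GetSpacing(), img.GetOrigin())
    return np.asarray(arr), grid


def read_volume(path: str | Path, quantity: str = "HU") -> ScalarVolume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd) scalar volume."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such volume file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # noqa: BLE001 - sitk raises bare RuntimeError
        raise VolumeIOError(f"could not read volume {path}: {exc}") from exc
    values, grid = _from_sitk(img)
    return ScalarVolume(grid, values.astype(float), quantity)


def write_volume(volume: ScalarVolume, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(_to_sitk(volume.values, volume.grid, np.float64), str(path))


def read_mask(path: str | Path, name: str | None = None) -> ROIMask:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such mask file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # noqa: BLE001
        raise VolumeIOError(f"could not read mask {path}: {exc}") from exc
    values, grid = _from_sitk(img)
    return ROIMask(grid, values > 0, name or path.stem.split(".")[0])


def write_mask(mask: ROIMask, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(
        _to_sitk(mask.values.astype(np.uint8), mask.grid, np.uint8), str(path)
    )


def write_structure_set(sset: StructureSet, directory: str | Path) -> None:
    """Write each mask as a uint8 NIfTI plus a JSON manifest naming the External."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"external": sset.external, "structures": {}}
    for name, mask in sset.masks.items():
        fname = f"{name}.nii.gz"
        write_mask(mask, directory / fname)
        manifest["structures"][name] = fname
    (directory / "structures.json").write_text(json.dumps(manifest, indent=2))


def read_structure_set(directory: str | Path) -> StructureSet:
    directory = Path(directory)
    manifest_path = directory / "structures.json"
    if not manifest_path.exists():
        raise VolumeIOError(f"no structures.json manifest in {directory}")
    manifest = json.loads(manifest_path.read_text())
    masks = {
        name: read_mask(directory / fname, name)
        for name, fname in manifest["structures"].items()
    }
    return StructureSet(masks, manifest["external"])


def write_deformation_field(field: DeformationField, path: str | Path) -> None:
    """Write a displacement field as a 3-vector NIfTI/NRRD image."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = field.displacement.transpose(2, 1, 0, 3)
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(tuple(float(s) for s in field.grid.spacing))
    img.SetOrigin(tuple(float(o) for o in field.grid.origin))
    sitk.WriteImage(img, str(path))


def read_deformation_field(path: str | Path) -> DeformationField:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such field file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # noqa: BLE001
        raise VolumeIOError(f"could not read field {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise VolumeIOError(f"{path} is not a 3-vector displacement field")
    disp = arr.transpose(2, 1, 0, 3).astype(float)
    grid = ImageGrid(disp.shape[:3], img.GetSpacing(), img.GetOrigin())
    return DeformationField(grid, disp)


# ---------------------------------------------------------------------------
# Resampling and mask algebra


def _check_overlap(source: ImageGrid, target: ImageGrid) -> None:
    lo_s, hi_s = source.extent()
    lo_t, hi_t = target.extent()
    if np.any(hi_s < lo_t) or np.any(hi_t < lo_s):
        raise ValueError("source and target grids do not overlap in world space")


def resample_to_grid(
    volume: ScalarVolume,
    target: ImageGrid,
    method: str = "trilinear",
    fill: float | None = None,
) -> ScalarVolume:
    """Resample a volume onto a target grid.

    ``method`` is ``trilinear`` or ``nearest``; voxels outside the source
    extent are filled with ``fill`` (default: -1000 for HU, 0 otherwise).
    """
    if method not in ("trilinear", "nearest"):
        raise ValueError(f"unknown resampling method {method!r}")
    _check_overlap(volume.grid, target)
    if volume.grid.same_as(target):
        return volume.copy()
    if fill is None:
        fill = _DEFAULT_FILL.get(volume.quantity, 0.0)
    coords = np.stack(
        [
            (ax_t[:, None, None] if a == 0 else ax_t[None, :, None] if a == 1 else ax_t[None, None, :])
            * np.ones(target.shape)
            for a, ax_t in enumerate(target.axes())
        ]
    )
    # world -> source continuous index
    for a in range(3):
        coords[a] = (coords[a] - volume.grid.origin[a]) / volume.grid.spacing[a]
    order = 1 if method == "trilinear" else 0
    out = ndimage.map_coordinates(
        volume.values, coords, order=order, mode="constant", cval=fill
    )
    return ScalarVolume(target, out, volume.quantity)


def resample_mask_to_grid(mask: ROIMask, target: ImageGrid) -> ROIMask:
    """Nearest-neighbour mask resampling; outside-extent voxels are False."""
    vol = ScalarVolume(mask.grid, mask.values.astype(float), "gamma")
    out = resample_to_grid(vol, target, method="nearest", fill=0.0)
    return ROIMask(target, out.values > 0.5, mask.name)


def erode_mask(mask: ROIMask, margin_mm: float) -> ROIMask:
    """Euclidean erosion by ``margin_mm`` in world millimetres.

    Computed on the world-space distance transform (anisotropic spacing
    aware): a voxel survives iff its center is more than ``margin_mm`` from
    the nearest background voxel center.  Margin 0 returns the input.
    """
    if margin_mm < 0:
        raise ValueError(f"erosion margin must be >= 0, got {margin_mm}")
    if margin_mm == 0 or not mask.values.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(mask.values, sampling=mask.grid.spacing)
    return ROIMask(mask.grid, dist > margin_mm, mask.name)


def intersect_masks(a: ROIMask, b: ROIMask, name: str | None = None) -> ROIMask:
    _require_same_grid(a, b)
    return ROIMask(a.grid, a.values & b.values, name or f"{a.name}&{b.name}")


def union_masks(a: ROIMask, b: ROIMask, name: str | None = None) -> ROIMask:
    _require_same_grid(a, b)
    return ROIMask(a.grid, a.values | b.values, name or f"{a.name}|{b.name}")


def subtract_masks(a: ROIMask, b: ROIMask, name: str | None = None) -> ROIMask:
    _require_same_grid(a, b)
    return ROIMask(a.grid, a.values & ~b.values, name or f"{a.name}-{b.name}")
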