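"""Volumetric data model, geometry conventions and NIfTI I/O.

Conventions used throughout the package
---------------------------------------
* Axes are fixed as ``(x, y, z) = (right→left, anterior→posterior,
  inferior→superior)`` and arrays are indexed ``values[i, j, k]`` in the
  same order.
* Voxel indices are 0-based.  The world coordinate (mm) of voxel
  ``(i, j, k)`` is ``origin + index * spacing``, i.e. coordinates refer to
  voxel *centres*.
* Displacement fields use the pull-back convention: for a reference voxel
  at world point ``p`` the moving image is sampled at ``p + offset(p)``.
* CT intensities are Hounsfield units in ``[-1024, 3071]``; dose volumes
  are physical Gy (or Gy_EQD2 after conversion) and non-negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

HU_AIR = -1000.0
HU_MIN = -1024.0
HU_MAX = 3071.0

#: Structure names recognised by :class:`StructureSet`.
STRUCTURE_NAMES = ("uterus", "rectum", "bladder", "body", "hrctv", "applicator")

#: The organs at risk evaluated by the DVH metrics.
OAR_NAMES = ("rectum", "bladder")


@dataclass(frozen=True)
class Grid:
    """A regular, axis-aligned 3D sampling grid (shape, spacing, origin)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("Grid requires 3D shape, spacing and origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be positive, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def world_axis(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def world_mesh(self, dtype=np.float64) -> list[np.ndarray]:
        """Dense meshgrid of world coordinates, one array per axis."""
        axes = [self.world_axis(a).astype(dtype) for a in range(3)]
        return np.meshgrid(*axes, indexing="ij")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world points (..., 3) to fractional voxel indices."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


@dataclass
class ScalarVolume:
    """A 3D scalar field (HU or Gy) on a regular grid."""

    values: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"ScalarVolume requires a 3D array, got {self.values.ndim}D"
            )
        if tuple(self.values.shape) != tuple(self.grid.shape):
            raise ValueError(
                f"array shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.grid.origin

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return self.grid.voxel_volume_cm3

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.values.copy(), self.grid)

    def with_values(self, values: np.ndarray) -> "ScalarVolume":
        return ScalarVolume(np.asarray(values), self.grid)


class StructureSet:
    """Named binary masks sharing one grid.

    The three organs at risk plus uterus must be pairwise disjoint and
    contained in the body contour; ``hrctv`` and ``applicator`` may overlap
    other structures (the HR-CTV covers cervix/uterus tissue and the
    applicator canal runs through it).
    """

    def __init__(self, masks: dict[str, np.ndarray], grid: Grid, validate: bool = True):
        self.grid = grid
        self.masks: dict[str, np.ndarray] = {}
        for name, mask in masks.items():
            mask = np.asarray(mask)
            if tuple(mask.shape) != tuple(grid.shape):
                raise ValueError(
                    f"mask '{name}' shape {mask.shape} does not match grid {grid.shape}"
                )
            self.masks[name] = mask.astype(bool)
        if validate:
            self.validate()

    def validate(self) -> None:
        organs = [n for n in ("uterus", "rectum", "bladder") if n in self.masks]
        for i, a in enumerate(organs):
            for b in organs[i + 1 :]:
                if np.any(self.masks[a] & self.masks[b]):
                    raise ValueError(f"structures '{a}' and '{b}' overlap")
        if "body" in self.masks:
            body = self.masks["body"]
            for name, mask in self.masks.items():
                if name != "body" and np.any(mask & ~body):
                    raise ValueError(f"structure '{name}' extends outside the body")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return list(self.masks)

    def volume_cm3(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.grid.voxel_volume_cm3

    def copy(self) -> "StructureSet":
        return StructureSet(
            {n: m.copy() for n, m in self.masks.items()}, self.grid, validate=False
        )


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion: rotate about a fixed centre, then translate.

    ``rotation_deg`` are extrinsic x-y-z Euler angles in degrees,
    ``translation_mm`` and ``center_mm`` are world-space millimetres.
    The forward map moves a point of the *moving* frame:
    ``F(q) = R (q - c) + c + t``.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        return (pts - c) @ self.matrix().T + c + t

    def inverse_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        return (pts - c - t) @ self.matrix() + c

    @property
    def is_identity(self) -> bool:
        return not (
            np.any(np.asarray(self.rotation_deg)) or np.any(np.asarray(self.translation_mm))
        )


@dataclass
class DisplacementField:
    """Dense per-voxel 3-vector offsets (mm) on a grid, pull-back convention."""

    offsets: np.ndarray  # shape (nx, ny, nz, 3)
    grid: Grid

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets)
        if self.offsets.ndim != 4 or self.offsets.shape[-1] != 3:
            raise ValueError("offsets must have shape (nx, ny, nz, 3)")
        if tuple(self.offsets.shape[:3]) != tuple(self.grid.shape):
            raise ValueError("offsets shape does not match grid")
        if not np.all(np.isfinite(self.offsets)):
            raise ValueError("displacement field contains non-finite values")

    @classmethod
    def identity(cls, grid: Grid) -> "DisplacementField":
        return cls(np.zeros(tuple(grid.shape) + (3,), dtype=np.float32), grid)

    @property
    def is_identity(self) -> bool:
        return not np.any(self.offsets)

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.offsets.astype(np.float64) ** 2, axis=-1))


# ---------------------------------------------------------------------------
# sampling / resampling
# ---------------------------------------------------------------------------


def _sample_at_index(
    values: np.ndarray, coords: list[np.ndarray], mode: str, fill: float
) -> np.ndarray:
    order = {"linear": 1, "nearest": 0}.get(mode)
    if order is None:
        raise ValueError(f"unknown interpolation mode '{mode}'")
    return ndimage.map_coordinates(
        values, coords, order=order, mode="grid-constant", cval=fill, prefilter=False
    )


def sample_at_world(
    volume: ScalarVolume, points_xyz: list[np.ndarray], mode: str = "linear", fill: float = 0.0
) -> np.ndarray:
    """Sample ``volume`` at world points given as three coordinate arrays."""
    coords = [
        (points_xyz[a] - volume.origin[a]) / volume.spacing[a] for a in range(3)
    ]
    return _sample_at_index(volume.values, coords, mode, fill)


def resample(
    volume: ScalarVolume, target: Grid, mode: str = "linear", fill: float = 0.0
) -> ScalarVolume:
    """Resample a volume onto ``target``; out-of-support voxels get ``fill``.

    Masks must be resampled with ``mode='nearest'`` (or warped through
    :func:`dirdose.registration.warp_mask`); CT uses ``fill=-1000`` HU and
    dose uses ``fill=0`` Gy.
    """
    lo_s, hi_s = volume.grid.bounds()
    lo_t, hi_t = target.bounds()
    if np.any(hi_s < lo_t) or np.any(hi_t < lo_s):
        raise ValueError("source and target grids are disjoint")
    if target == volume.grid:
        return ScalarVolume(volume.values.copy(), target)
    mesh = target.world_mesh(dtype=np.float32)
    out = sample_at_world(volume, mesh, mode=mode, fill=fill)
    return ScalarVolume(out.astype(volume.values.dtype, copy=False), target)


def apply_rigid(
    volume: ScalarVolume,
    transform: RigidTransform,
    mode: str = "linear",
    fill: float = 0.0,
    target: Grid | None = None,
) -> ScalarVolume:
    """Resample ``volume`` with a rigid motion applied (push-forward).

    The output voxel at world point ``p`` takes the value of the input at
    ``F⁻¹(p)``, so the image content moves by ``F``.
    """
    target = target or volume.grid
    if transform.is_identity:
        return resample(volume, target, mode=mode, fill=fill)
    mesh = target.world_mesh(dtype=np.float64)
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    src = transform.inverse_points(pts)
    coords = [
        (src[:, a].reshape(target.shape) - volume.origin[a]) / volume.spacing[a]
        for a in range(3)
    ]
    out = _sample_at_index(volume.values, coords, mode, fill)
    return ScalarVolume(out.astype(volume.values.dtype, copy=False), target)


def warp_volume(
    volume: ScalarVolume,
    field: DisplacementField,
    mode: str = "linear",
    fill: float = 0.0,
) -> ScalarVolume:
    """Pull-back warp: output voxel at ``p`` samples ``volume`` at ``p + u(p)``.

    The output lives on the field's grid.  An identity field on the
    volume's own grid is an exact no-op.
    """
    if field.grid == volume.grid:
        if field.is_identity:
            return ScalarVolume(volume.values.copy(), field.grid)
        # index-space arithmetic avoids float round-off from world conversion
        idx = np.meshgrid(*[np.arange(n, dtype=np.float32) for n in field.grid.shape],
                          indexing="ij")
        coords = [
            idx[a] + field.offsets[..., a] / volume.spacing[a] for a in range(3)
        ]
    else:
        mesh = field.grid.world_mesh(dtype=np.float32)
        coords = [
            (mesh[a] + field.offsets[..., a] - volume.origin[a]) / volume.spacing[a]
            for a in range(3)
        ]
    out = _sample_at_index(volume.values, coords, mode, fill)
    return ScalarVolume(out.astype(volume.values.dtype, copy=False), field.grid)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def read_volume(path: str | Path) -> ScalarVolume:
    """Read a 3D single-channel NIfTI volume.

    The affine must be axis-aligned (diagonal, positive); grid metadata is
    preserved to double precision.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"expected a 3D volume, got {data.ndim}D payload in {path.name}"
        )
    aff = img.affine
    lin = aff[:3, :3]
    if np.any(np.abs(lin - np.diag(np.diag(lin))) > 1e-6):
        raise ValueError(f"non-axis-aligned affine in {path.name} is not supported")
    spacing = tuple(np.diag(lin))
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive spacing {spacing} in {path.name}")
    origin = tuple(aff[:3, 3])
    return ScalarVolume(data, Grid(tuple(data.shape), spacing, origin))


def write_volume(volume: ScalarVolume, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(volume.values), volume.grid.affine())
    nib.save(img, str(path))


def read_field(path: str | Path) -> DisplacementField:
    """Read a displacement field stored as a 4D NIfTI with 3 components."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"expected (nx, ny, nz, 3) field, got shape {data.shape}")
    aff = img.affine
    spacing = tuple(np.diag(aff[:3, :3]))
    origin = tuple(aff[:3, 3])
    return DisplacementField(data, Grid(tuple(data.shape[:3]), spacing, origin))


def write_field(field: DisplacementField, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(field.offsets, dtype=np.float32),
                          field.grid.affine())
    nib.save(img, str(path))


def read_structures(directory: str | Path, grid: Grid | None = None) -> StructureSet:
    """Read a structure set from ``directory/structures.json`` sidecar."""
    directory = Path(directory)
    sidecar = directory / "structures.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing structure sidecar: {sidecar}")
    mapping = json.loads(sidecar.read_text())
    masks = {}
    ref_grid = grid
    for name, rel in mapping.items():
        vol = read_volume(directory / rel)
        if ref_grid is None:
            ref_grid = vol.grid
        masks[name] = vol.values > 0.5
    assert ref_grid is not None
    return StructureSet(masks, ref_grid)


def write_structures(structs: StructureSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mapping = {}
    for name, mask in structs.masks.items():
        rel = f"{name}.nii.gz"
        write_volume(
            ScalarVolume(mask.astype(np.uint8), structs.grid), directory / rel
        )
        mapping[name] = rel
    (directory / "structures.json").write_text(json.dumps(mapping, indent=1))
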