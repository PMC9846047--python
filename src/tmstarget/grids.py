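"""Reference voxel grid, gray-matter mask, and signed brain maps.

All model-level vectors (local effect, stimulation network, pathological
network) live on the gray-matter voxels of a shared :class:`VoxelGrid`.
World coordinates are MNI-style mm; voxel indices are 0-based; the affine
maps voxel index -> world mm (the dominant neuroimaging convention, so
external NIfTI volumes drop in unchanged).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DataError, DegenerateMapError, IncompatibleGridError

__all__ = [
    "VoxelGrid",
    "BrainMap",
    "read_volume",
    "write_volume",
    "map_correlation",
]

#: tolerance for declaring two affines / shapes "the same grid"
AFFINE_ATOL = 1e-4


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel lattice with an index->mm affine and a gray-matter mask.

    Parameters
    ----------
    shape
        Voxels per axis, length-3.
    affine
        4x4 homogeneous transform taking 0-based voxel indices to world mm.
    gm_mask
        Boolean array of ``shape`` marking gray-matter voxels; ``N`` is the
        number of True entries and every model vector has length ``N``.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    gm_mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        mask = np.asarray(self.gm_mask, dtype=bool)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "gm_mask", mask)
        if affine.shape != (4, 4):
            raise DataError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise DataError("affine is not invertible")
        if mask.shape != self.shape:
            raise DataError(f"mask shape {mask.shape} != grid shape {self.shape}")
        if not mask.any():
            raise DataError("gray-matter mask is empty (N >= 1 required)")

    @property
    def n_voxels(self) -> int:
        """Number of gray-matter voxels N."""
        return int(self.gm_mask.sum())

    @property
    def mask_indices(self) -> np.ndarray:
        """(N, 3) integer voxel indices of the gray-matter voxels, C order."""
        return np.array(np.nonzero(self.gm_mask)).T

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm via the affine."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) world mm to (fractional) voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    @property
    def mask_coords_mm(self) -> np.ndarray:
        """(N, 3) world-mm centers of the gray-matter voxels."""
        return self.voxel_to_world(self.mask_indices)

    def same_grid(self, other: "VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.affine, other.affine, atol=AFFINE_ATOL)
            and bool(np.array_equal(self.gm_mask, other.gm_mask))
        )

    def require_same_grid(self, other: "VoxelGrid") -> None:
        if not self.same_grid(other):
            raise IncompatibleGridError("objects are not defined on the same voxel grid")

    # ------------------------------------------------------------------ I/O
    def to_json(self, path: str | Path, mask_path: str | Path) -> None:
        """Write grid description (shape, affine, mask volume path) as JSON."""
        mask_img = nib.Nifti1Image(self.gm_mask.astype(np.uint8), self.affine)
        nib.save(mask_img, str(mask_path))
        payload = {
            "shape": list(self.shape),
            "affine": self.affine.tolist(),
            "mask": str(mask_path),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "VoxelGrid":
        payload = json.loads(Path(path).read_text())
        mask_img = nib.load(payload["mask"])
        mask = np.asarray(mask_img.dataobj) > 0
        return cls(tuple(payload["shape"]), np.array(payload["affine"]), mask)

    @classmethod
    def from_mask_volume(cls, path: str | Path) -> "VoxelGrid":
        """Build a grid from a mask NIfTI (nonzero voxels are gray matter)."""
        img = nib.load(str(path))
        mask = np.asarray(img.dataobj) > 0
        return cls(tuple(img.shape[:3]), np.asarray(img.affine), mask)


@dataclass(frozen=True)
class BrainMap:
    """A signed real vector over the gray-matter voxels of a grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", values)
        if values.shape != (self.grid.n_voxels,):
            raise DataError(
                f"values length {values.size} != N={self.grid.n_voxels}"
            )
        if not np.all(np.isfinite(values)):
            raise DataError("brain map contains non-finite values inside the mask")

    def to_volume(self) -> np.ndarray:
        """Embed the masked vector into a full 3D array (zero outside mask)."""
        vol = np.zeros(self.grid.shape, dtype=float)
        vol[self.grid.gm_mask] = self.values
        return vol

    def __neg__(self) -> "BrainMap":
        return BrainMap(self.grid, -self.values)

    def __sub__(self, other: "BrainMap") -> "BrainMap":
        self.grid.require_same_grid(other.grid)
        return BrainMap(self.grid, self.values - other.values)


def read_volume(path: str | Path, grid: VoxelGrid | None = None) -> BrainMap:
    """Read a 3D NIfTI volume as a :class:`BrainMap`.

    If ``grid`` is given, the volume's shape and affine are validated against
    it and values are restricted to its gray-matter mask. Otherwise a grid is
    constructed with a full (all-True) mask.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several flavors
        raise DataError(f"cannot read volume {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DataError(f"expected a 3D volume, got shape {data.shape}")
    if grid is None:
        grid = VoxelGrid(data.shape, np.asarray(img.affine), np.ones(data.shape, bool))
    else:
        if tuple(data.shape) != grid.shape or not np.allclose(
            img.affine, grid.affine, atol=AFFINE_ATOL
        ):
            raise IncompatibleGridError(
                f"volume {path} does not match the reference grid "
                f"(shape {data.shape} vs {grid.shape})"
            )
    return BrainMap(grid, data[grid.gm_mask])


def write_volume(brain_map: BrainMap, path: str | Path) -> None:
    """Write a :class:`BrainMap` as a 3D NIfTI volume (zero outside the mask)."""
    img = nib.Nifti1Image(brain_map.to_volume().astype(np.float64), brain_map.grid.affine)
    nib.save(img, str(path))


def _check_variance(values: np.ndarray, name: str) -> None:
    if np.ptp(values) == 0.0:
        raise DegenerateMapError(f"map {name!r} is constant over the mask")


def map_correlation(a: BrainMap, b: BrainMap) -> float:
    """Pearson correlation of two maps over gray-matter voxels.

    Raw Pearson on values (not ranks, not Fisher-z); both maps must be
    non-constant over the mask.
    """
    a.grid.require_same_grid(b.grid)
    _check_variance(a.values, "a")
    _check_variance(b.values, "b")
    x = a.values - a.values.mean()
    y = b.values - b.values.mean()
    r = float(x @ y / np.sqrt((x @ x) * (y @ y)))
    return float(np.clip(r, -1.0, 1.0))
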