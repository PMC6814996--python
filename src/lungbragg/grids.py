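"""Voxel grids, structure masks and phantoms.

All geometry lives on regular rectilinear grids.  World coordinates are in
millimetres, attached to voxel *centers*: the center of voxel ``(i, j, k)``
is ``origin + (i, j, k) * spacing``.  Grid values are relative densities
(water = 1.0, dimensionless) unless a :class:`VoxelGrid` is reused to hold
another scalar field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

Triple = Tuple[float, float, float]


@dataclass
class VoxelGrid:
    """A scalar field on a regular 3-D grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar field (relative density for phantoms).  Must be finite and
        non-negative.
    spacing : triple of float
        Voxel size in mm along each axis; strictly positive.
    origin : triple of float
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: Triple
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("VoxelGrid values must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be > 0 on all axes, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite everywhere")
        if np.any(self.values < 0):
            raise ValueError("grid values must be >= 0")

    @property
    def dims(self) -> Tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of a single voxel in cm^3."""
        return float(np.prod(self.spacing)) / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.dims[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world points (…, 3) to fractional index coordinates."""
        p = np.asarray(points_mm, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.values.copy(), self.spacing, self.origin)


@dataclass
class StructureMask:
    """A named boolean mask aligned to a :class:`VoxelGrid`."""

    name: str
    mask: np.ndarray
    spacing: Triple
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("StructureMask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @classmethod
    def from_grid(cls, name: str, mask: np.ndarray, grid: VoxelGrid) -> "StructureMask":
        if mask.shape != grid.dims:
            raise ValueError(f"mask shape {mask.shape} != grid dims {grid.dims}")
        return cls(name, mask, grid.spacing, grid.origin)

    @property
    def dims(self) -> Tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cm3(self) -> float:
        """Structure volume: voxel count x voxel volume."""
        return self.n_voxels * float(np.prod(self.spacing)) / 1000.0

    def centroid_mm(self) -> np.ndarray:
        """World position of the mask's center of mass."""
        if self.n_voxels == 0:
            raise ValueError(f"structure '{self.name}' is empty")
        idx = np.argwhere(self.mask).mean(axis=0)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def aligned_to(self, grid: VoxelGrid) -> bool:
        return (
            self.dims == grid.dims
            and np.allclose(self.spacing, grid.spacing)
            and np.allclose(self.origin, grid.origin)
        )


@dataclass
class Phantom:
    """Density grid plus lung mask and named structures (CTV required).

    Invariants checked at construction: every structure is aligned to the
    density grid; lung voxel densities lie in (0, 1); the CTV (solid tumor)
    does not overlap the lung mask.
    """

    density: VoxelGrid
    lung_mask: StructureMask
    structures: Dict[str, StructureMask] = field(default_factory=dict)
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lung_mask.aligned_to(self.density):
            raise ValueError("lung_mask not aligned to density grid")
        for name, s in self.structures.items():
            if not s.aligned_to(self.density):
                raise ValueError(f"structure '{name}' not aligned to density grid")
        if "CTV" not in self.structures:
            raise ValueError("phantom requires a CTV structure")
        lung = self.lung_mask.mask
        if lung.any():
            dl = self.density.values[lung]
            if dl.min() <= 0 or dl.max() >= 1:
                raise ValueError("lung voxel densities must lie strictly in (0, 1)")
        if np.any(self.structures["CTV"].mask & lung):
            raise ValueError("CTV must not overlap the lung mask (tumor is solid tissue)")

    @property
    def ctv(self) -> StructureMask:
        return self.structures["CTV"]

    def structure(self, name: str) -> StructureMask:
        return self.structures[name]


def grid_like(grid: VoxelGrid, values: Optional[np.ndarray] = None) -> VoxelGrid:
    """A new grid with the same geometry (zeros unless values given)."""
    v = np.zeros(grid.dims) if values is None else values
    return VoxelGrid(v, grid.spacing, grid.origin)
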