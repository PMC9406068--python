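"""Regular 3-D voxel grids.

All volumes in this package (densities, masks, dose, displacement fields)
live on an axis-aligned regular grid. World coordinates are millimetres,
voxel indices are 0-based, and ``world = origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Grid:
    """Geometry of a regular voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along each axis (3 ints, each >= 1).
    spacing_mm
        Voxel size along each axis in mm (3 positive floats).
    origin_mm
        World position of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing_mm) != 3:
            raise ValueError("grid shape and spacing must be 3-vectors")
        if any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be positive, got {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size of the grid along each axis."""
        return np.asarray(self.shape) * np.asarray(self.spacing_mm)

    @property
    def center_mm(self) -> np.ndarray:
        """World coordinates of the grid centre."""
        return np.asarray(self.origin_mm) + (np.asarray(self.shape) - 1) * np.asarray(self.spacing_mm) / 2.0

    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (for NIfTI I/O)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centres, as a sparse meshgrid."""
        axes = [
            self.origin_mm[k] + np.arange(self.shape[k]) * self.spacing_mm[k]
            for k in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Convert world coordinates (..., 3) to fractional voxel indices."""
        p = np.asarray(points_mm, dtype=float)
        return (p - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def same_geometry(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=tol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=tol)
        )


def check_same_grid(grid: Grid, *arrays: np.ndarray) -> None:
    for a in arrays:
        if tuple(a.shape[:3]) != grid.shape:
            raise ValueError(f"array shape {a.shape} does not match grid {grid.shape}")
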