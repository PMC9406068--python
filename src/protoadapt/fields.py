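"""Smooth displacement fields and mask/image warping.

Displacement fields stand in for the output of deformable image
registration and for interfraction anatomical change.  A field ``u``
assigns each voxel a 3-vector in mm, and warping is defined as a
pull-back: ``out(x) = in(x + u(x))``.  A zero field is the identity.

Masks are transported as level sets: the 0/1 indicator is linearly
interpolated at the displaced sample position and thresholded at 0.5,
which avoids the single-voxel holes nearest-neighbour sampling produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import Grid, check_same_grid


@dataclass(frozen=True)
class DisplacementField:
    """Per-voxel displacement vectors in mm, shape ``(*grid.shape, 3)``."""

    grid: Grid
    vectors_mm: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors_mm, dtype=np.float64)
        if v.shape != (*self.grid.shape, 3):
            raise ValueError(
                f"field shape {v.shape} does not match grid {self.grid.shape} + (3,)"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("displacement field contains non-finite values")
        object.__setattr__(self, "vectors_mm", v)

    @classmethod
    def zero(cls, grid: Grid) -> "DisplacementField":
        return cls(grid, np.zeros((*grid.shape, 3)))

    def __add__(self, other: "DisplacementField") -> "DisplacementField":
        # Small-deformation composition: displacements add.
        if not self.grid.same_geometry(other.grid):
            raise ValueError("cannot add fields on different grids")
        return DisplacementField(self.grid, self.vectors_mm + other.vectors_mm)

    def __neg__(self) -> "DisplacementField":
        return DisplacementField(self.grid, -self.vectors_mm)

    def max_magnitude_mm(self) -> float:
        return float(np.sqrt((self.vectors_mm**2).sum(axis=-1)).max())


def smooth_random_field(
    grid: Grid,
    amplitude_mm: float,
    correlation_length_mm: float,
    seed,
    divergence_free: bool = False,
) -> DisplacementField:
    """Zero-mean Gaussian random displacement field.

    Each component is Gaussian-filtered white noise with filter width
    ``correlation_length_mm``, recentred to zero mean and rescaled so the
    empirical per-component standard deviation equals ``amplitude_mm``
    (exactly in the generic case, to within a few percent in the
    divergence-free case, where a single scale factor must be shared by
    the components).  Deterministic in ``seed``.

    With ``divergence_free=True`` the field is the curl of a smoothed
    random vector potential, so it is volume-preserving to first order —
    the right model for interfractional organ *motion*, which rearranges
    tissue without creating or destroying it.  Contour-error fields (a
    registration can legitimately over- or under-segment) should keep
    the default compressible form.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be >= 0")
    if correlation_length_mm <= 0:
        raise ValueError("correlation_length_mm must be > 0")
    if amplitude_mm == 0:
        return DisplacementField.zero(grid)
    rng = np.random.default_rng(seed)
    sigma_vox = [correlation_length_mm / s for s in grid.spacing_mm]

    def smoothed() -> np.ndarray:
        white = rng.standard_normal(grid.shape)
        return ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")

    if not divergence_free:
        comps = []
        for _ in range(3):
            smooth = smoothed()
            smooth -= smooth.mean()
            sd = smooth.std()
            comps.append(np.zeros(grid.shape) if sd == 0 else smooth * (amplitude_mm / sd))
        return DisplacementField(grid, np.stack(comps, axis=-1))

    # u = curl(A): exactly divergence-free in the continuum, to finite-
    # difference accuracy on the grid
    A = [smoothed() for _ in range(3)]
    sp = grid.spacing_mm
    dAz_dy = np.gradient(A[2], sp[1], axis=1)
    dAy_dz = np.gradient(A[1], sp[2], axis=2)
    dAx_dz = np.gradient(A[0], sp[2], axis=2)
    dAz_dx = np.gradient(A[2], sp[0], axis=0)
    dAy_dx = np.gradient(A[1], sp[0], axis=0)
    dAx_dy = np.gradient(A[0], sp[1], axis=1)
    comps = [dAz_dy - dAy_dz, dAx_dz - dAz_dx, dAy_dx - dAx_dy]
    comps = [c - c.mean() for c in comps]
    rms = np.sqrt(np.mean([c.var() for c in comps]))
    scale = 0.0 if rms == 0 else amplitude_mm / rms
    return DisplacementField(grid, np.stack([c * scale for c in comps], axis=-1))


def uniform_field(grid: Grid, displacement_mm) -> DisplacementField:
    """Constant field; ``warp`` with ``-t`` translates content by ``+t``."""
    u = np.broadcast_to(np.asarray(displacement_mm, dtype=float), (*grid.shape, 3))
    return DisplacementField(grid, u.copy())


def _sample_coordinates(field: DisplacementField) -> np.ndarray:
    """Fractional voxel indices of ``x + u(x)`` for every voxel, shape (3, N)."""
    grid = field.grid
    idx = np.indices(grid.shape, dtype=np.float64)
    spacing = np.asarray(grid.spacing_mm)
    coords = np.empty_like(idx)
    for k in range(3):
        coords[k] = idx[k] + field.vectors_mm[..., k] / spacing[k]
    return coords.reshape(3, -1)


def warp_mask(mask: np.ndarray, field: DisplacementField) -> np.ndarray:
    """Transport a boolean mask by a displacement field (level-set warp).

    Samples outside the grid are treated as background.
    """
    check_same_grid(field.grid, mask)
    coords = _sample_coordinates(field)
    vals = ndimage.map_coordinates(
        mask.astype(np.float32), coords, order=1, mode="constant", cval=0.0
    )
    return (vals >= 0.5).reshape(field.grid.shape)


def warp_scalar(image: np.ndarray, field: DisplacementField, background: float = 0.0) -> np.ndarray:
    """Transport a scalar image (e.g. density) by linear interpolation."""
    check_same_grid(field.grid, image)
    coords = _sample_coordinates(field)
    vals = ndimage.map_coordinates(
        image.astype(np.float64), coords, order=1, mode="constant", cval=background
    )
    return vals.reshape(field.grid.shape)
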