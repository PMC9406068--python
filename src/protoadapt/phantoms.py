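"""Synthetic planning/daily anatomies for two treatment sites.

Two analytic phantom templates are provided, matching the two constraint
sets the study uses:

``abdomen``
    A stereotactic upper-abdominal case: a pancreatic-head-like CTV
    surrounded by stomach, small/large bowel, duodenum, spinal cord,
    kidneys and liver.  OAR limits outrank target coverage.
``head_neck``
    A standard-fractionation head-and-neck case: nested high/low-risk
    CTVs with brainstem, spinal cord, pharyngeal constrictors, larynx
    and parotids.  Target coverage outranks OAR limits.

All shapes are ellipsoids or capsules placed relative to the grid
centre, so templates rasterize onto any sufficiently large grid.
Densities are relative stopping powers (water = 1).  Per-fraction
anatomical change is modelled as one displacement field — rigid shift,
smooth random organ motion, optional target scaling and an external
shrink emulating weight loss — applied consistently to the density and
every structure mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .fields import DisplacementField, smooth_random_field, uniform_field, warp_mask, warp_scalar
from .grids import Grid
from .structures import Structure, StructureSet

AIR_DENSITY = 0.0012
TEMPLATES = ("abdomen", "head_neck")

# Internal smoothness scale of the interfractional organ-motion field (mm).
ORGAN_MOTION_CORRELATION_MM = 30.0


# --------------------------------------------------------------------------
# shape primitives


def _ellipsoid(grid: Grid, center_mm: np.ndarray, radii_mm: np.ndarray) -> np.ndarray:
    X, Y, Z = grid.voxel_centers_mm()
    c, r = center_mm, radii_mm
    return ((X - c[0]) / r[0]) ** 2 + ((Y - c[1]) / r[1]) ** 2 + ((Z - c[2]) / r[2]) ** 2 <= 1.0


def _capsule(grid: Grid, p0_mm: np.ndarray, p1_mm: np.ndarray, radius_mm: float) -> np.ndarray:
    """Cylinder with hemispherical caps between two axis points."""
    X, Y, Z = grid.voxel_centers_mm()
    d = p1_mm - p0_mm
    L2 = float(d @ d)
    px, py, pz = X - p0_mm[0], Y - p0_mm[1], Z - p0_mm[2]
    if L2 == 0:
        t = 0.0
    else:
        t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / L2, 0.0, 1.0)
    dx = px - t * d[0]
    dy = py - t * d[1]
    dz = pz - t * d[2]
    return dx**2 + dy**2 + dz**2 <= radius_mm**2


def _ecylinder(
    grid: Grid, center_mm: np.ndarray, radii_mm: np.ndarray, z0_mm: float, z1_mm: float
) -> np.ndarray:
    """Elliptic cylinder along z with flat ends (body-outline primitive)."""
    X, Y, Z = grid.voxel_centers_mm()
    inside = ((X - center_mm[0]) / radii_mm[0]) ** 2 + ((Y - center_mm[1]) / radii_mm[1]) ** 2 <= 1.0
    return inside & (Z >= z0_mm) & (Z <= z1_mm)


def _rasterize_shape(grid: Grid, shape: dict, center_mm: np.ndarray) -> np.ndarray:
    kind = shape["type"]
    if kind == "ecylinder":
        c = center_mm + np.asarray(shape["center"], dtype=float)
        return _ecylinder(
            grid,
            c,
            np.asarray(shape["radii"], dtype=float),
            center_mm[2] + float(shape["zmin"]),
            center_mm[2] + float(shape["zmax"]),
        )
    if kind == "ellipsoid":
        return _ellipsoid(
            grid,
            center_mm + np.asarray(shape["center"], dtype=float),
            np.asarray(shape["radii"], dtype=float),
        )
    if kind == "capsule":
        return _capsule(
            grid,
            center_mm + np.asarray(shape["p0"], dtype=float),
            center_mm + np.asarray(shape["p1"], dtype=float),
            float(shape["radius"]),
        )
    raise ValueError(f"unknown shape type {kind!r}")


def _shape_bounds(shape: dict) -> tuple[np.ndarray, np.ndarray]:
    """Bounding box (lo, hi) of a primitive, relative to the grid centre."""
    if shape["type"] == "ecylinder":
        c = np.asarray(shape["center"], dtype=float)
        r = np.asarray(shape["radii"], dtype=float)
        lo = np.array([c[0] - r[0], c[1] - r[1], float(shape["zmin"])])
        hi = np.array([c[0] + r[0], c[1] + r[1], float(shape["zmax"])])
        return lo, hi
    if shape["type"] == "ellipsoid":
        c = np.asarray(shape["center"], dtype=float)
        r = np.asarray(shape["radii"], dtype=float)
        return c - r, c + r
    c0 = np.asarray(shape["p0"], dtype=float)
    c1 = np.asarray(shape["p1"], dtype=float)
    r = float(shape["radius"])
    return np.minimum(c0, c1) - r, np.maximum(c0, c1) + r


# --------------------------------------------------------------------------
# template geometry


def default_geometry(template: str, seed=None, jitter_mm: float = 0.0) -> dict[str, dict]:
    """Analytic organ geometry for a template, optionally jittered.

    Returns a mapping ``name -> {"role", "shapes", "density"}`` with all
    shape coordinates in mm relative to the grid centre.  With a seed and
    a positive ``jitter_mm``, organ centres are perturbed and radii scaled
    by up to ±5% to emulate inter-patient variation; the external contour
    is never jittered so the body outline stays stable.
    """
    if template == "abdomen":
        geo: dict[str, dict[str, Any]] = {
            "external": {
                "role": "external",
                "density": 1.0,
                "shapes": [{"type": "ecylinder", "center": [0, 0, 0], "radii": [112, 86],
                            "zmin": -92, "zmax": 92}],
            },
            "ctv": {
                "role": "target",
                "density": 1.02,
                "shapes": [{"type": "ellipsoid", "center": [24, 2, 0], "radii": [25, 22, 20]}],
            },
            "liver": {
                "role": "oar",
                "density": 1.05,
                "shapes": [{"type": "ellipsoid", "center": [-46, -6, 2], "radii": [56, 58, 56]}],
            },
            "stomach": {
                "role": "oar",
                "density": 1.0,
                "shapes": [{"type": "ellipsoid", "center": [-6, -34, 26], "radii": [28, 22, 20]}],
            },
            "duodenum": {
                "role": "oar",
                "density": 1.0,
                "shapes": [{"type": "capsule", "p0": [14, -28, -24], "p1": [34, -28, 24], "radius": 9}],
            },
            "small_bowel": {
                "role": "oar",
                "density": 1.0,
                "shapes": [{"type": "ellipsoid", "center": [34, -36, -34], "radii": [34, 24, 26]}],
            },
            "large_bowel": {
                "role": "oar",
                "density": 1.0,
                "shapes": [{"type": "capsule", "p0": [-28, -36, 0], "p1": [70, -36, 0], "radius": 12}],
            },
            "spinal_cord": {
                "role": "oar",
                "density": 1.0,
                "shapes": [{"type": "capsule", "p0": [-8, 56, -76], "p1": [-8, 56, 76], "radius": 6}],
            },
            "kidneys": {
                "role": "oar",
                "density": 1.03,
                "shapes": [
                    {"type": "ellipsoid", "center": [-48, 36, -24], "radii": [22, 16, 30]},
                    {"type": "ellipsoid", "center": [52, 36, -24], "radii": [22, 16, 30]},
                ],
            },
        }
        bone = {"type": "capsule", "p0": [-8, 56, -78], "p1": [-8, 56, 78], "radius": 14}
    elif template == "head_neck":
        geo = {
            "external": {
                "role": "external",
                "density": 1.0,
                "shapes": [{"type": "ecylinder", "center": [0, 0, 0], "radii": [72, 72],
                            "zmin": -91, "zmax": 88}],
            },
            "high_risk_ctv": {
                "role": "target",
                "density": 1.02,
                "shapes": [{"type": "ellipsoid", "center": [0, 6, -10], "radii": [30, 27, 24]}],
            },
            "low_risk_ctv": {
                "role": "target",
                "density": 1.02,
                "shapes": [{"type": "ellipsoid", "center": [0, 8, -20], "radii": [44, 36, 38]}],
            },
            "brainstem": {
                "role": "oar",
                "density": 1.04,
                "shapes": [{"type": "capsule", "p0": [0, 46, 20], "p1": [0, 40, 70], "radius": 8}],
            },
            "spinal_cord": {
                "role": "oar",
                "density": 1.04,
                "shapes": [{"type": "capsule", "p0": [0, 56, -76], "p1": [0, 54, 20], "radius": 5.5}],
            },
            "constrictors": {
                "role": "oar",
                "density": 1.0,
                "shapes": [{"type": "capsule", "p0": [0, 36, -60], "p1": [0, 36, -10], "radius": 7}],
            },
            "larynx": {
                "role": "oar",
                "density": 0.7,
                "shapes": [{"type": "ellipsoid", "center": [0, 18, -66], "radii": [16, 14, 16]}],
            },
            "parotids": {
                "role": "oar",
                "density": 1.0,
                "shapes": [
                    {"type": "ellipsoid", "center": [-54, 20, 5], "radii": [13, 12, 20]},
                    {"type": "ellipsoid", "center": [54, 20, 5], "radii": [13, 12, 20]},
                ],
            },
        }
        bone = {"type": "capsule", "p0": [0, 49, -78], "p1": [0, 49, 24], "radius": 11}
    else:
        raise ValueError(f"unknown template {template!r}; expected one of {TEMPLATES}")

    if seed is not None and jitter_mm > 0:
        rng = np.random.default_rng(seed)
        for name, entry in geo.items():
            if entry["role"] == "external":
                continue
            for shape in entry["shapes"]:
                offset = np.clip(
                    rng.normal(0.0, jitter_mm, size=3), -2 * jitter_mm, 2 * jitter_mm
                )
                scale = 1.0 + rng.uniform(-0.05, 0.05)
                if shape["type"] == "ellipsoid":
                    shape["center"] = (np.asarray(shape["center"]) + offset).tolist()
                    shape["radii"] = (np.asarray(shape["radii"]) * scale).tolist()
                else:
                    shape["p0"] = (np.asarray(shape["p0"]) + offset).tolist()
                    shape["p1"] = (np.asarray(shape["p1"]) + offset).tolist()
                    shape["radius"] = float(shape["radius"]) * scale
    geo["__bone__"] = {"role": "density_only", "density": 1.45, "shapes": [bone]}
    return geo


DEFAULT_GRIDS = {
    "abdomen": ((60, 48, 48), (4.0, 4.0, 4.0)),
    "head_neck": ((48, 48, 54), (3.5, 3.5, 3.5)),
}


# --------------------------------------------------------------------------
# phantom types


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic planning anatomy."""

    template: str
    grid_shape: tuple[int, int, int] | None = None
    spacing_mm: tuple[float, float, float] | None = None
    organ_geometry: dict[str, dict] | None = None
    density_background: float = AIR_DENSITY
    seed: int = 0

    def resolved_grid(self) -> Grid:
        if self.template not in TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}; expected one of {TEMPLATES}")
        shape, spacing = DEFAULT_GRIDS[self.template]
        shape = self.grid_shape or shape
        spacing = self.spacing_mm or spacing
        if any(int(n) < 16 for n in shape):
            raise ValueError(f"grid shape must be >= 16 per axis, got {shape}")
        return Grid(tuple(shape), tuple(spacing))


@dataclass
class Phantom:
    """One anatomy instance: density grid + ground-truth structures."""

    grid: Grid
    density: np.ndarray  # relative stopping power, float32
    clinical_structures: StructureSet
    template: str
    fraction_index: int = 0

    def __post_init__(self) -> None:
        if self.density.shape != self.grid.shape:
            raise ValueError("density shape does not match grid")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        if not any(
            self.clinical_structures[n].mask.any() for n in self.clinical_structures.targets()
        ):
            raise ValueError("phantom target mask is empty")


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize a planning phantom (fraction 0) from its spec.

    Deterministic: the same spec always produces the same density and
    masks.  Errors if a shape extends outside the grid or if the target
    rasterizes to an empty mask.
    """
    grid = spec.resolved_grid()
    geometry = spec.organ_geometry or default_geometry(spec.template)
    center = grid.center_mm

    density = np.full(grid.shape, spec.density_background, dtype=np.float64)
    structures: dict[str, Structure] = {}
    # external first so organ densities paint over soft tissue
    order = sorted(geometry, key=lambda n: geometry[n]["role"] != "external")
    for name in order:
        entry = geometry[name]
        mask = np.zeros(grid.shape, dtype=bool)
        half_span = (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing_mm) / 2.0
        for shape in entry["shapes"]:
            lo, hi = _shape_bounds(shape)
            if np.any(lo < -half_span - 1e-9) or np.any(hi > half_span + 1e-9):
                raise ValueError(f"shape of structure {name!r} extends outside the grid")
            mask |= _rasterize_shape(grid, shape, center)
        density[mask] = entry.get("density", 1.0)
        if entry["role"] != "density_only":
            structures[name] = Structure(mask, entry["role"])

    if spec.template == "head_neck" and "low_risk_ctv" in structures:
        # the low-risk CTV contains the high-risk CTV by definition
        structures["low_risk_ctv"].mask |= structures["high_risk_ctv"].mask

    priority = "stereotactic" if spec.template == "abdomen" else "coverage"
    sset = StructureSet(grid, structures, priority_mode=priority)
    for name in sset.targets():
        if not sset[name].mask.any():
            raise ValueError(f"target {name!r} rasterized to an empty mask")
    return Phantom(grid, density.astype(np.float32), sset, spec.template, fraction_index=0)


# --------------------------------------------------------------------------
# interfractional change


@dataclass(frozen=True)
class AnatomyChangeModel:
    """Stochastic model of day-to-day anatomical change.

    rigid_shift_sd_mm
        SD of a random rigid shift of the whole anatomy (setup-like).
    organ_displacement_amp_mm
        Per-component SD of a smooth random deformation emulating
        interfractional bowel/GI motion.
    target_volume_scale
        Multiplicative target volume change per fraction (1 = none).
    external_shrink_fraction
        Fractional loss of external-contour volume (weight loss), in
        [0, 0.3].
    """

    rigid_shift_sd_mm: float = 0.0
    organ_displacement_amp_mm: float = 0.0
    target_volume_scale: float = 1.0
    external_shrink_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rigid_shift_sd_mm < 0 or self.organ_displacement_amp_mm < 0:
            raise ValueError("change amplitudes must be >= 0")
        if not (0.0 <= self.external_shrink_fraction <= 0.3):
            raise ValueError("external_shrink_fraction must lie in [0, 0.3]")
        if self.target_volume_scale <= 0:
            raise ValueError("target_volume_scale must be > 0")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _scaling_field(
    grid: Grid,
    center_mm: np.ndarray,
    radii_mm: np.ndarray,
    linear_scale: float,
    full_from: float,
    zero_below: float,
    transverse_only: bool = False,
) -> DisplacementField:
    """Radial pull-back scaling field around an ellipsoidal region.

    For normalized radius rho >= ``full_from`` the pull-back samples at
    ``center + (x - center)/scale``, which maps the region boundary
    exactly to ``scale`` times its radius; below ``zero_below`` the field
    vanishes, with a smoothstep ramp in between.  With
    ``transverse_only`` the scaling acts in the x-y plane only (weight
    loss shrinks the body cross-section, not its length).
    """
    X, Y, Z = grid.voxel_centers_mm()
    if transverse_only:
        rho = np.sqrt(
            ((X - center_mm[0]) / radii_mm[0]) ** 2
            + ((Y - center_mm[1]) / radii_mm[1]) ** 2
        )
    else:
        rho = np.sqrt(
            ((X - center_mm[0]) / radii_mm[0]) ** 2
            + ((Y - center_mm[1]) / radii_mm[1]) ** 2
            + ((Z - center_mm[2]) / radii_mm[2]) ** 2
        )
    s = _smoothstep((rho - zero_below) / (full_from - zero_below))
    factor = (1.0 / linear_scale - 1.0) * s
    u = np.empty((*grid.shape, 3))
    u[..., 0] = factor * (X - center_mm[0])
    u[..., 1] = factor * (Y - center_mm[1])
    u[..., 2] = 0.0 if transverse_only else factor * (Z - center_mm[2])
    return DisplacementField(grid, u)


def _mask_extents(mask: np.ndarray, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Centroid (mm) and half-extents (mm) of a mask's bounding box."""
    idx = np.argwhere(mask)
    lo = idx.min(axis=0) * np.asarray(grid.spacing_mm) + np.asarray(grid.origin_mm)
    hi = idx.max(axis=0) * np.asarray(grid.spacing_mm) + np.asarray(grid.origin_mm)
    centroid = idx.mean(axis=0) * np.asarray(grid.spacing_mm) + np.asarray(grid.origin_mm)
    return centroid, (hi - lo) / 2.0


def sample_change_field(
    planning: Phantom, model: AnatomyChangeModel, fraction_index: int
) -> DisplacementField:
    """Draw the displacement field for one fraction (deterministic in seed)."""
    grid = planning.grid
    total = DisplacementField.zero(grid)
    if model.rigid_shift_sd_mm > 0:
        rng = np.random.default_rng([int(model.seed) % (2**31), fraction_index, 0])
        shift = rng.normal(0.0, model.rigid_shift_sd_mm, size=3)
        # pull-back with -t translates content by +t
        total = total + uniform_field(grid, -shift)
    if model.organ_displacement_amp_mm > 0:
        # volume-preserving: organs shift and squeeze past each other
        # without net tissue creation/loss
        total = total + smooth_random_field(
            grid,
            model.organ_displacement_amp_mm,
            ORGAN_MOTION_CORRELATION_MM,
            [int(model.seed) % (2**31), fraction_index, 1],
            divergence_free=True,
        )
    if model.external_shrink_fraction > 0:
        ext = planning.clinical_structures["external"].mask
        c, radii = _mask_extents(ext, grid)
        # transverse shrink: volume scales with the square of the factor
        lam = (1.0 - model.external_shrink_fraction) ** 0.5
        total = total + _scaling_field(
            grid, c, radii, lam, full_from=0.6, zero_below=0.4, transverse_only=True
        )
    if model.target_volume_scale != 1.0:
        tname = planning.clinical_structures.targets()[0]
        tmask = planning.clinical_structures[tname].mask
        c, radii = _mask_extents(tmask, grid)
        lam = model.target_volume_scale ** (1.0 / 3.0)
        total = total + _scaling_field(grid, c, radii, lam, full_from=1.05, zero_below=1.8)
    return total


def apply_anatomy_change(
    planning: Phantom, field: DisplacementField, fraction_index: int
) -> Phantom:
    """Warp density and all structures by one shared field.

    The same field transports the density and every mask, so image and
    structures can never disagree by construction.  Errors if the warped
    target empties or reaches the grid boundary.
    """
    density = warp_scalar(planning.density, field, background=AIR_DENSITY)
    structures = {
        name: Structure(warp_mask(s.mask, field), s.role)
        for name, s in planning.clinical_structures.structures.items()
    }
    for name, s in structures.items():
        if planning.clinical_structures[name].role != "target":
            continue
        if not s.mask.any():
            raise ValueError(f"deformation emptied target {name!r}")
        idx = np.argwhere(s.mask)
        if (idx.min(axis=0) == 0).any() or (
            idx.max(axis=0) >= np.asarray(planning.grid.shape) - 1
        ).any():
            raise ValueError(f"deformation pushed target {name!r} outside the grid")
    sset = StructureSet(
        planning.grid, structures, planning.clinical_structures.priority_mode
    )
    return Phantom(
        planning.grid,
        density.astype(np.float32),
        sset,
        planning.template,
        fraction_index=fraction_index,
    )


def generate_fraction(
    planning: Phantom, model: AnatomyChangeModel, fraction_index: int
) -> Phantom:
    """Generate the daily anatomy for one fraction.

    The returned phantom's structures are the ground-truth ("clinical")
    contours for that day.  With all change amplitudes zero the daily
    phantom equals the planning phantom.
    """
    if fraction_index < 1:
        raise ValueError("fraction_index must be >= 1 for daily anatomies")
    if (
        model.rigid_shift_sd_mm == 0
        and model.organ_displacement_amp_mm == 0
        and model.target_volume_scale == 1.0
        and model.external_shrink_fraction == 0
    ):
        return Phantom(
            planning.grid,
            planning.density.copy(),
            planning.clinical_structures.copy_with(
                {
                    n: Structure(s.mask.copy(), s.role)
                    for n, s in planning.clinical_structures.structures.items()
                }
            ),
            planning.template,
            fraction_index=fraction_index,
        )
    field = sample_change_field(planning, model, fraction_index)
    return apply_anatomy_change(planning, field, fraction_index)
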