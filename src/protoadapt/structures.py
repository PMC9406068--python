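"""Contour-ensemble algebra and dose metrics.

This module implements the set operations used to combine contour
ensembles propagated by several registration algorithms (union,
intersection, per-voxel agreement frequencies and the exact-level
agreement substructures), plus the volume and DVH metrics needed to
express and evaluate clinical constraints.

Conventions fixed here and documented in the methods note:

* ``V(d)`` counts voxels with dose **>= d** (closed threshold).
* The max-dose metric is the maximum voxel dose in the structure.
* Agreement substructures are exact-level partitions: for a K-set
  ensemble the level ``round(100*k/K)`` contains exactly the voxels
  included by exactly ``k`` sets.  For K = 3 the labels are 33/67/100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .grids import Grid, check_same_grid

Role = Literal["target", "oar", "external"]
PriorityMode = Literal["stereotactic", "coverage"]


@dataclass
class Structure:
    mask: np.ndarray  # boolean
    role: Role

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.role not in ("target", "oar", "external"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class StructureSet:
    """Named boolean masks sharing one grid.

    A voxel may belong to several structures; overlaps are deliberately
    kept and handled downstream by the optimizer's objective terms.
    """

    grid: Grid
    structures: dict[str, Structure]
    priority_mode: PriorityMode = "coverage"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.priority_mode not in ("stereotactic", "coverage"):
            raise ValueError(f"unknown priority_mode {self.priority_mode!r}")
        for name, s in self.structures.items():
            check_same_grid(self.grid, s.mask)
        if not any(s.role == "target" for s in self.structures.values()):
            raise ValueError("structure set must contain at least one target")

    def __getitem__(self, name: str) -> Structure:
        return self.structures[name]

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    @property
    def names(self) -> list[str]:
        return list(self.structures)

    def targets(self) -> list[str]:
        return [n for n, s in self.structures.items() if s.role == "target"]

    def mask(
        self, name: str, exclude: str | None = None, exclude_margin_mm: float = 0.0
    ) -> np.ndarray:
        """Mask of ``name``, optionally minus another structure.

        The exclusion form mirrors clinical notation like "Liver (-GTV)":
        dose-limit rows on a container structure are evaluated outside the
        boosted substructure it contains.  A positive margin additionally
        excludes the dose-gradient shell around the subtracted structure.
        """
        m = self.structures[name].mask
        if exclude is not None:
            m = m & ~expand_mask(self.structures[exclude].mask, self.grid, exclude_margin_mm)
        return m

    def copy_with(self, structures: dict[str, Structure]) -> "StructureSet":
        return StructureSet(self.grid, structures, self.priority_mode)


def expand_mask(mask: np.ndarray, grid: Grid, margin_mm: float) -> np.ndarray:
    """Mask dilated by an isotropic margin (mm); no-op for margin <= 0."""
    if margin_mm <= 0:
        return mask
    from scipy import ndimage

    dist = ndimage.distance_transform_edt(~mask, sampling=grid.spacing_mm)
    return dist <= margin_mm


def _check_masks(masks: Sequence[np.ndarray]) -> list[np.ndarray]:
    if len(masks) < 1:
        raise ValueError("need at least one mask")
    masks = [np.asarray(m, dtype=bool) for m in masks]
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise ValueError(f"mask shape mismatch: {m.shape} vs {shape}")
    return masks


def union(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Voxelwise OR of the masks."""
    masks = _check_masks(masks)
    out = masks[0].copy()
    for m in masks[1:]:
        out |= m
    return out


def intersection(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Voxelwise AND of the masks."""
    masks = _check_masks(masks)
    out = masks[0].copy()
    for m in masks[1:]:
        out &= m
    return out


@dataclass
class AgreementMap:
    """Per-structure voxel agreement fraction over a K-set ensemble.

    ``counts[name]`` holds, per voxel, how many of the K sets include
    that voxel; ``fraction(name)`` is counts / K in [0, 1].  The value is
    1 exactly on the ensemble intersection and > 0 exactly on the union.
    """

    grid: Grid
    n_sets: int
    counts: dict[str, np.ndarray]  # uint8 per structure

    def fraction(self, name: str) -> np.ndarray:
        return self.counts[name].astype(np.float64) / self.n_sets


def agreement_map(ensemble: Sequence[StructureSet]) -> AgreementMap:
    """Per-voxel mean of indicator masks, per structure."""
    if len(ensemble) < 2:
        raise ValueError("agreement map needs at least two structure sets")
    roster = set(ensemble[0].names)
    grid = ensemble[0].grid
    for s in ensemble[1:]:
        if not s.grid.same_geometry(grid):
            raise ValueError("ensemble members live on different grids")
        missing = roster.symmetric_difference(s.names)
        if missing:
            raise ValueError(f"structure roster mismatch: {sorted(missing)}")
    counts = {}
    for name in ensemble[0].names:
        c = np.zeros(grid.shape, dtype=np.uint8)
        for s in ensemble:
            c += s[name].mask
        counts[name] = c
    return AgreementMap(grid, len(ensemble), counts)


@dataclass
class SubstructureSet:
    """Exact-level agreement substructures: level label (%) -> mask."""

    grid: Grid
    n_sets: int
    levels: dict[str, dict[int, np.ndarray]]  # name -> {label: mask}


def substructure_partition(agreement: AgreementMap, n_sets: int | None = None) -> SubstructureSet:
    """Partition the ensemble union into exact agreement levels.

    For each k in 1..K the level labelled ``round(100*k/K)`` contains the
    voxels included by exactly k ensemble members.  Levels are pairwise
    disjoint and their union is the ensemble union.
    """
    K = agreement.n_sets if n_sets is None else n_sets
    if K != agreement.n_sets:
        raise ValueError(f"partition level count {K} != ensemble size {agreement.n_sets}")
    levels: dict[str, dict[int, np.ndarray]] = {}
    for name, counts in agreement.counts.items():
        if counts.max(initial=0) > K:
            raise ValueError(f"agreement counts for {name!r} exceed ensemble size {K}")
        levels[name] = {
            int(round(100.0 * k / K)): counts == k for k in range(1, K + 1)
        }
    return SubstructureSet(agreement.grid, K, levels)


def level_fraction(label: int, n_sets: int) -> float:
    """Exact agreement fraction k/K corresponding to a rounded % label."""
    for k in range(1, n_sets + 1):
        if int(round(100.0 * k / n_sets)) == label:
            return k / n_sets
    raise ValueError(f"label {label} is not a level of a {n_sets}-set ensemble")


def conservative_combination(
    ensemble: Sequence[StructureSet], priority_mode: PriorityMode
) -> StructureSet:
    """Combine an ensemble into one conservative structure set.

    Organs at risk always take the union of the propagated masks.  The
    target takes the intersection under a stereotactic priority (organ
    limits outrank coverage, so the smallest defensible target is used)
    and the union under a coverage priority (largest possible target).
    An empty target intersection is flagged as a warning, not an error.
    """
    amap = agreement_map(ensemble)
    out: dict[str, Structure] = {}
    warnings: list[str] = []
    for name in ensemble[0].names:
        role = ensemble[0][name].role
        masks = [s[name].mask for s in ensemble]
        if role == "target" and priority_mode == "stereotactic":
            m = intersection(masks)
            if not m.any():
                warnings.append(f"conservative target {name!r} intersection is empty")
        else:
            m = union(masks)
        out[name] = Structure(m, role)
    result = StructureSet(ensemble[0].grid, out, priority_mode)
    result.warnings = warnings
    return result


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 if both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def volume_cc(mask: np.ndarray, grid: Grid) -> float:
    """Mask volume in cm³ (voxel count x voxel volume)."""
    check_same_grid(grid, np.asarray(mask))
    return int(np.asarray(mask, dtype=bool).sum()) * grid.voxel_volume_mm3 / 1000.0


# --- dose metrics ----------------------------------------------------------

MetricKind = Literal["v_percent", "v_cc", "mean", "max", "sparing_cc"]


@dataclass(frozen=True)
class MetricSpec:
    """One DVH-type metric.

    kind:
      v_percent  -- volume with dose >= level, as % of the structure
      v_cc       -- volume with dose >= level, in cm³
      mean       -- mean structure dose (Gy-RBE)
      max        -- maximum voxel dose (Gy-RBE)
      sparing_cc -- volume with dose < level, in cm³ ("V_tot - V(d)")
    """

    kind: MetricKind
    dose_level: float | None = None  # Gy-RBE; None for mean/max

    def __post_init__(self) -> None:
        if self.kind in ("v_percent", "v_cc", "sparing_cc") and self.dose_level is None:
            raise ValueError(f"metric {self.kind} requires a dose level")

    @property
    def unit(self) -> str:
        return {"v_percent": "%", "v_cc": "cc", "mean": "Gy", "max": "Gy", "sparing_cc": "cc"}[self.kind]


def dose_metric(dose: np.ndarray, mask: np.ndarray, spec: MetricSpec, grid: Grid) -> float:
    """Evaluate one dose metric on a structure. Empty masks are an error."""
    check_same_grid(grid, dose, np.asarray(mask))
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("dose metric on an empty mask")
    d = np.asarray(dose, dtype=np.float64)[mask]
    vox_cc = grid.voxel_volume_mm3 / 1000.0
    if spec.kind == "v_percent":
        return 100.0 * int((d >= spec.dose_level).sum()) / n
    if spec.kind == "v_cc":
        return int((d >= spec.dose_level).sum()) * vox_cc
    if spec.kind == "sparing_cc":
        return int((d < spec.dose_level).sum()) * vox_cc
    if spec.kind == "mean":
        return float(d.mean())
    if spec.kind == "max":
        return float(d.max())
    raise ValueError(f"unknown metric kind {spec.kind!r}")


def dvh_curve(
    dose: np.ndarray, mask: np.ndarray, grid: Grid, bin_width_gy: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative DVH: (dose levels, % of structure with dose >= level).

    Starts at 100% at 0 Gy and is monotone non-increasing.
    """
    if bin_width_gy <= 0:
        raise ValueError("bin width must be > 0")
    mask = np.asarray(mask, dtype=bool)
    check_same_grid(grid, dose, mask)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("DVH of an empty mask")
    d = np.asarray(dose, dtype=np.float64)[mask]
    top = max(float(d.max()), 0.0) + bin_width_gy
    levels = np.arange(0.0, top + bin_width_gy, bin_width_gy)
    volume = np.array([100.0 * (d >= lv).sum() / n for lv in levels])
    return levels, volume
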