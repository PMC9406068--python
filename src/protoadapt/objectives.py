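"""Penalty objectives for spot-weight optimization.

Standard one-sided quadratic penalties plus quota-based DVH penalties,
with analytic gradients.  Each term is zero exactly when its clinical
goal is met.  DVH terms penalize only the smallest set of voxels whose
doses must move to satisfy the volume quota: an upper DVH constraint
pushes down the lowest-dose voxels exceeding the level beyond the
allowed volume, a lower one pushes up the highest-dose voxels still
below the level until the required volume is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Literal, Sequence

import numpy as np

from .constraints import ConstraintSpec
from .grids import Grid
from .structures import StructureSet

TermKind = Literal["min_dose", "max_dose", "mean_upper", "dvh_upper", "dvh_lower"]


@dataclass(frozen=True)
class ObjectiveTerm:
    """One penalty term on one structure.

    kind / parameters:
      min_dose   -- quadratic underdose penalty below ``dose_level``
      max_dose   -- quadratic overdose penalty above ``dose_level``
      mean_upper -- (mean - volume_param)^2 above the mean limit
                    (``volume_param`` holds the mean limit in Gy)
      dvh_upper  -- V(dose_level) <= volume_param cc
      dvh_lower  -- V(dose_level) >= volume_param %
    """

    structure: str
    kind: TermKind
    dose_level: float
    volume_param: float = 0.0
    weight: float = 1.0
    exclude: str | None = None
    exclude_margin_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("min_dose", "max_dose", "mean_upper", "dvh_upper", "dvh_lower"):
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.weight < 0:
            raise ValueError("term weight must be >= 0")
        if self.dose_level < 0:
            raise ValueError("dose level must be >= 0")


def term_value_and_gradient(
    term: ObjectiveTerm,
    dose_flat: np.ndarray,
    mask_indices: np.ndarray,
    voxel_cc: float,
) -> tuple[float, np.ndarray]:
    """Unweighted term value and its gradient w.r.t. the masked doses.

    Returns ``(value, grad)`` where ``grad`` has one entry per mask
    voxel (same order as ``mask_indices``).  The value is >= 0 and zero
    iff the term's goal is satisfied.
    """
    n = len(mask_indices)
    if n == 0:
        raise ValueError("objective term on an empty mask")
    d = dose_flat[mask_indices]
    grad = np.zeros(n)
    level = term.dose_level

    if term.kind == "min_dose":
        r = np.maximum(0.0, level - d)
        value = float((r**2).sum() / n)
        grad = -2.0 * r / n
    elif term.kind == "max_dose":
        r = np.maximum(0.0, d - level)
        value = float((r**2).sum() / n)
        grad = 2.0 * r / n
    elif term.kind == "mean_upper":
        limit = term.volume_param
        e = max(0.0, float(d.mean()) - limit)
        value = e * e
        grad[:] = 2.0 * e / n
    elif term.kind == "dvh_upper":
        quota = term.volume_param / voxel_cc  # allowed voxels >= level
        over = np.nonzero(d > level)[0]
        n_keep = int(np.floor(quota))
        if len(over) > n_keep:
            # spare the hottest n_keep voxels, push the rest down to the level
            order = np.argsort(d[over])[::-1]
            push = over[order[n_keep:]]
            r = d[push] - level
            value = float((r**2).sum() / n)
            grad[push] = 2.0 * r / n
        else:
            value = 0.0
    elif term.kind == "dvh_lower":
        n_req = int(np.ceil(term.volume_param / 100.0 * n))
        have = int((d >= level).sum())
        if have < n_req:
            below = np.nonzero(d < level)[0]
            order = np.argsort(d[below])[::-1]  # closest to the level first
            lift = below[order[: n_req - have]]
            r = level - d[lift]
            value = float((r**2).sum() / n)
            grad[lift] = -2.0 * r / n
        else:
            value = 0.0
    else:  # pragma: no cover
        raise ValueError(term.kind)
    return value, grad


@dataclass
class BoundTerm:
    term: ObjectiveTerm
    mask_indices: np.ndarray
    weight: float  # term.weight x any replication factor


@dataclass
class CompositeObjective:
    """Weighted sum of penalty terms bound to voxel index sets."""

    grid: Grid
    terms: list[BoundTerm]
    label: str = ""
    skipped: list[str] = dc_field(default_factory=list)

    def value_and_gradient(self, dose_flat: np.ndarray) -> tuple[float, np.ndarray]:
        total = 0.0
        grad = np.zeros(dose_flat.shape[0])
        vox_cc = self.grid.voxel_volume_mm3 / 1000.0
        for bt in self.terms:
            v, g = term_value_and_gradient(bt.term, dose_flat, bt.mask_indices, vox_cc)
            total += bt.weight * v
            # mask indices are unique within a term, so fancy-index add is safe
            grad[bt.mask_indices] += bt.weight * g
        return total, grad

    def value(self, dose_flat: np.ndarray) -> float:
        total = 0.0
        vox_cc = self.grid.voxel_volume_mm3 / 1000.0
        for bt in self.terms:
            v, _ = term_value_and_gradient(bt.term, dose_flat, bt.mask_indices, vox_cc)
            total += bt.weight * v
        return total


@dataclass(frozen=True)
class ObjectiveConfig:
    """How clinical constraints map to optimization terms.

    The planning sheet gives hard/soft priorities, not numeric weights;
    hard rows get ``hard_weight`` and soft rows ``soft_weight`` (10:1 by
    default).  Each target-coverage row also spawns an auxiliary uniform
    min-dose term at the same level (factor ``aux_min_dose_factor``) so
    the whole target, not just the DVH quota, is pulled up.  An optional
    weak max-dose cap on the external contour discourages dose dumps in
    unconstrained tissue.
    """

    hard_weight: float = 10.0
    soft_weight: float = 1.0
    aux_min_dose_factor: float = 0.5
    external_max_gy: float | None = None
    external_weight: float = 0.5


# provider returns (voxel indices, weight factor, quota share) triples
MaskProvider = Callable[[str, str | None, float], list[tuple[np.ndarray, float, float]]]


def default_mask_provider(sset: StructureSet) -> MaskProvider:
    def provider(name: str, exclude: str | None, margin_mm: float) -> list[tuple[np.ndarray, float, float]]:
        mask = sset.mask(name, exclude, margin_mm)
        return [(np.nonzero(mask.ravel())[0], 1.0, 1.0)]

    return provider


def terms_from_constraints(
    constraints: Sequence[ConstraintSpec], config: ObjectiveConfig
) -> list[ObjectiveTerm]:
    """Translate constraint rows into penalty terms (structure-agnostic)."""
    terms: list[ObjectiveTerm] = []
    for c in constraints:
        w = config.hard_weight if c.importance == "hard" else config.soft_weight
        k = c.metric.kind
        margin = c.exclude_margin_mm
        if k == "v_percent" and c.direction == "lower":
            terms.append(
                ObjectiveTerm(c.structure, "dvh_lower", c.metric.dose_level, c.limit, w,
                              c.exclude, margin)
            )
            if config.aux_min_dose_factor > 0:
                terms.append(
                    ObjectiveTerm(
                        c.structure,
                        "min_dose",
                        c.metric.dose_level,
                        0.0,
                        w * config.aux_min_dose_factor,
                        c.exclude,
                        margin,
                    )
                )
        elif k == "v_cc" and c.direction == "upper":
            terms.append(
                ObjectiveTerm(c.structure, "dvh_upper", c.metric.dose_level, c.limit, w,
                              c.exclude, margin)
            )
        elif k == "mean":
            terms.append(ObjectiveTerm(c.structure, "mean_upper", 0.0, c.limit, w, c.exclude, margin))
        elif k == "max":
            terms.append(ObjectiveTerm(c.structure, "max_dose", c.limit, 0.0, w, c.exclude, margin))
        elif k == "sparing_cc":
            # Vtot - V(d) > Q cc  <=>  V(d) <= (structure volume - Q) cc;
            # the volume is structure-set dependent, so store the sparing
            # quota and resolve it at binding time via a negative marker.
            terms.append(
                ObjectiveTerm(c.structure, "dvh_upper", c.metric.dose_level, -c.limit, w,
                              c.exclude, margin)
            )
        else:
            raise ValueError(f"cannot map constraint {c.serialize()!r} to an objective")
    return terms


def build_composite(
    constraints: Sequence[ConstraintSpec],
    sset: StructureSet,
    config: ObjectiveConfig,
    mask_provider: MaskProvider | None = None,
    label: str = "",
) -> CompositeObjective:
    """Bind constraint-derived terms to a structure set's voxels.

    ``mask_provider`` maps a structure name to one or more (voxel
    indices, weight factor, quota share) triples; the probabilistic
    strategy supplies one triple per agreement level with weight factor
    k/K and quota share proportional to the level's volume, so absolute
    volume limits (cc) are apportioned rather than replicated.  Terms
    whose mask is empty are skipped and recorded on the composite.
    """
    provider = mask_provider if mask_provider is not None else default_mask_provider(sset)
    vox_cc = sset.grid.voxel_volume_mm3 / 1000.0
    bound: list[BoundTerm] = []
    skipped: list[str] = []
    for term in terms_from_constraints(constraints, config):
        for idx, frac, quota_share in provider(term.structure, term.exclude, term.exclude_margin_mm):
            if len(idx) == 0:
                skipped.append(f"{term.structure}:{term.kind}")
                continue
            t = term
            if term.kind == "dvh_upper" and term.volume_param < 0:
                # sparing rule: resolve the allowed hot volume against this
                # mask's actual volume (quota share apportions the rule)
                quota = max(0.0, len(idx) * vox_cc + term.volume_param * quota_share)
                t = ObjectiveTerm(
                    term.structure, "dvh_upper", term.dose_level, quota, term.weight,
                    term.exclude, term.exclude_margin_mm
                )
            elif term.kind == "dvh_upper" and quota_share != 1.0:
                t = ObjectiveTerm(
                    term.structure, "dvh_upper", term.dose_level,
                    term.volume_param * quota_share, term.weight,
                    term.exclude, term.exclude_margin_mm
                )
            bound.append(BoundTerm(t, idx, t.weight * frac))
    if config.external_max_gy is not None and "external" in sset:
        idx = np.nonzero(sset["external"].mask.ravel())[0]
        if len(idx):
            t = ObjectiveTerm("external", "max_dose", config.external_max_gy, 0.0, config.external_weight)
            bound.append(BoundTerm(t, idx, t.weight))
    return CompositeObjective(sset.grid, bound, label=label, skipped=skipped)
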