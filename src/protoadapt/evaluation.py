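"""Plan-quality scoring and study aggregation.

Every plan, whatever structures it was optimized on, is evaluated on
the *clinical* (ground-truth) structures.  Each violated constraint
contributes the absolute exceedance |C − C_ref| in its native unit
(Gy, cc, or percentage points), optionally scaled by a score weight;
the contributions are summed into a single plan-quality score in
arbitrary units (au).  A score of 0 means every constraint is met; a
value exactly at its limit is not a violation.

Patient-to-patient differences are removed by differencing each score
against the reference-adaptation score of the same phantom/fraction;
per-strategy means and ranges of those differences mirror the study's
reporting.  A weight-sensitivity sweep re-scores stored per-constraint
contributions under target-only and organ-only multipliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constraints import ConstraintSpec
from .structures import StructureSet, dose_metric


@dataclass(frozen=True)
class ConstraintResult:
    spec: ConstraintSpec
    value: float  # evaluated C, native unit
    violated: bool

    @property
    def contribution(self) -> float:
        if not self.violated:
            return 0.0
        return abs(self.value - self.spec.limit) * self.spec.score_weight


def evaluate_constraints(
    dose: np.ndarray,
    clinical: StructureSet,
    constraints: Sequence[ConstraintSpec],
) -> list[ConstraintResult]:
    """Evaluate every constraint row on the clinical structures.

    A value exactly at the limit is not a violation.  Missing structures
    raise a KeyError naming the structure.
    """
    out = []
    for c in constraints:
        if c.structure not in clinical:
            raise KeyError(f"structure {c.structure!r} missing from clinical set")
        if c.exclude is not None and c.exclude not in clinical:
            raise KeyError(f"exclusion structure {c.exclude!r} missing from clinical set")
        mask = clinical.mask(c.structure, c.exclude, c.exclude_margin_mm)
        value = dose_metric(dose, mask, c.metric, clinical.grid)
        if c.direction == "upper":
            violated = value > c.limit
        else:
            violated = value < c.limit
        out.append(ConstraintResult(c, float(value), bool(violated)))
    return out


@dataclass
class ScoreReport:
    """Per-constraint contributions and their total (au) for one plan."""

    results: list[ConstraintResult]
    strategy: str = ""
    fraction_index: int = 0

    @property
    def total(self) -> float:
        return float(sum(r.contribution for r in self.results))

    @property
    def n_violated(self) -> int:
        return sum(r.violated for r in self.results)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "constraint": [r.spec.serialize() for r in self.results],
                "structure": [r.spec.structure for r in self.results],
                "value": [r.value for r in self.results],
                "limit": [r.spec.limit for r in self.results],
                "unit": [r.spec.metric.unit for r in self.results],
                "violated": [r.violated for r in self.results],
                "contribution_au": [r.contribution for r in self.results],
            }
        )


def score(
    dose: np.ndarray,
    clinical: StructureSet,
    constraints: Sequence[ConstraintSpec],
    strategy: str = "",
    fraction_index: int = 0,
) -> ScoreReport:
    """Score one plan's dose on the clinical structures."""
    return ScoreReport(
        evaluate_constraints(dose, clinical, constraints), strategy, fraction_index
    )


def score_difference(report: ScoreReport, reference: ScoreReport) -> float:
    """Signed score difference to the reference adaptation (au)."""
    a = [r.spec.serialize() for r in report.results]
    b = [r.spec.serialize() for r in reference.results]
    if a != b:
        raise ValueError("score difference requires identical constraint lists")
    return report.total - reference.total


# --------------------------------------------------------------------------
# study tables


@dataclass
class StudyTable:
    """Per-(phantom, fraction, strategy) scores plus per-strategy summary."""

    records: pd.DataFrame  # template, phantom, fraction, strategy, score, score_diff
    summary: pd.DataFrame  # template, strategy -> mean/min/max of score_diff


def aggregate(records: pd.DataFrame) -> StudyTable:
    """Mean and range of score differences per strategy and template."""
    if len(records) == 0:
        raise ValueError("no study records to aggregate")
    summary = (
        records.groupby(["template", "strategy"])["score_diff"]
        .agg(["mean", "min", "max"])
        .reset_index()
    )
    return StudyTable(records.reset_index(drop=True), summary)


@dataclass
class SensitivityReport:
    """Strategy rankings under target/organ score-weight multipliers."""

    table: pd.DataFrame  # template, mode, multiplier, strategy, mean_diff, rank
    best_stable: dict[str, bool]
    worst_stable: dict[str, bool]

    @property
    def conclusion_stable(self) -> bool:
        return all(self.best_stable.values()) and all(self.worst_stable.values())


def sensitivity_analysis(
    contributions: pd.DataFrame,
    multipliers: Iterable[float] = range(1, 11),
    reference_strategy: str = "reference",
) -> SensitivityReport:
    """Re-rank strategies under target-only / organ-only weight boosts.

    ``contributions`` is the long table of per-constraint contributions
    with columns template, phantom, fraction, strategy, structure_role,
    contribution_au.  For each multiplier m, either all target rows or
    all organ rows are weighted m times more than the rest; totals and
    mean score differences to the reference are recomputed and the
    strategies re-ranked per template.
    """
    required = {"template", "phantom", "fraction", "strategy", "structure_role", "contribution_au"}
    missing = required - set(contributions.columns)
    if missing:
        raise ValueError(f"contributions table missing columns {sorted(missing)}")

    rows = []
    for mode in ("target", "organ"):
        role = "target" if mode == "target" else "oar"
        for m in multipliers:
            scaled = contributions.assign(
                scaled=contributions["contribution_au"]
                * np.where(contributions["structure_role"] == role, float(m), 1.0)
            )
            totals = (
                scaled.groupby(["template", "phantom", "fraction", "strategy"])["scaled"]
                .sum()
                .reset_index()
            )
            ref = totals[totals["strategy"] == reference_strategy].rename(
                columns={"scaled": "ref_total"}
            )[["template", "phantom", "fraction", "ref_total"]]
            merged = totals.merge(ref, on=["template", "phantom", "fraction"])
            merged["diff"] = merged["scaled"] - merged["ref_total"]
            means = (
                merged.groupby(["template", "strategy"])["diff"].mean().reset_index()
            )
            for template, grp in means.groupby("template"):
                ranked = grp.sort_values("diff", kind="mergesort").reset_index(drop=True)
                for rank, rec in ranked.iterrows():
                    rows.append(
                        {
                            "template": template,
                            "mode": mode,
                            "multiplier": float(m),
                            "strategy": rec["strategy"],
                            "mean_diff": rec["diff"],
                            "rank": int(rank) + 1,
                        }
                    )
    table = pd.DataFrame(rows)

    best_stable, worst_stable = {}, {}
    for template, grp in table.groupby("template"):
        bests = set()
        worsts = set()
        for (mode, m), sub in grp.groupby(["mode", "multiplier"]):
            sub = sub.sort_values("rank")
            bests.add(sub.iloc[0]["strategy"])
            worsts.add(sub.iloc[-1]["strategy"])
        best_stable[template] = len(bests) == 1
        worst_stable[template] = len(worsts) == 1
    return SensitivityReport(table, best_stable, worst_stable)
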