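"""Clinical constraint specifications and their text dialect.

Constraints are written in the compact dialect used on planning sheets,
e.g. ``"stomach: V33Gy < 1 cc [hard]"`` or ``"kidneys: mean < 10Gy
[hard]"``.  The sparing form ``"liver: Vtot-V15Gy > 700 cc"`` requires
the structure volume receiving less than 15 Gy to exceed 700 cm³.
A structure may carry an exclusion, ``"low_risk_ctv (-high_risk_ctv+10mm)"``,
meaning the row is evaluated on the container minus the boosted
substructure (plus an optional dose-gradient margin) — the usual reading
of dose limits on a structure that contains a higher-prescription volume.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import yaml

from .structures import MetricSpec

Importance = Literal["hard", "soft"]
Direction = Literal["upper", "lower"]


@dataclass(frozen=True)
class ConstraintSpec:
    """One clinical constraint row.

    ``limit`` is C_ref in the metric's native unit (%, cc or Gy);
    ``direction`` says whether the evaluated value must stay below
    ("upper") or above ("lower") the limit.  ``score_weight`` scales the
    row's contribution to the plan-quality score (default 1).
    """

    structure: str
    metric: MetricSpec
    limit: float
    direction: Direction
    importance: Importance = "hard"
    score_weight: float = 1.0
    exclude: str | None = None
    exclude_margin_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.limit < 0:
            raise ValueError("limit must be >= 0")
        if self.direction not in ("upper", "lower"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.importance not in ("hard", "soft"):
            raise ValueError(f"bad importance {self.importance!r}")
        if self.score_weight < 0:
            raise ValueError("score_weight must be >= 0")

    # ---- text dialect ----------------------------------------------------

    _ROW = re.compile(
        r"^\s*(?P<structure>[^:(]+?)\s*(?:\(\s*-\s*(?P<exclude>[^)]+?)\s*\))?\s*:\s*"
        r"(?P<body>.+?)\s*(?:\[(?P<importance>hard|soft)\])?\s*$"
    )
    _V = re.compile(r"^V\s*(?P<d>\d+(?:\.\d+)?)\s*(?:Gy)?\s*(?P<op>[<>])\s*(?P<lim>\d+(?:\.\d+)?)\s*(?P<unit>%|cc)$")
    _SPARING = re.compile(
        r"^V_?tot_?\s*-\s*V\s*(?P<d>\d+(?:\.\d+)?)\s*(?:Gy)?\s*>\s*(?P<lim>\d+(?:\.\d+)?)\s*cc$"
    )
    _SCALAR = re.compile(r"^(?P<kind>mean|max)\s*<\s*(?P<lim>\d+(?:\.\d+)?)\s*(?:Gy)?$")

    @classmethod
    def parse(cls, text: str, score_weight: float = 1.0) -> "ConstraintSpec":
        m = cls._ROW.match(text)
        if not m:
            raise ValueError(f"cannot parse constraint row {text!r}")
        structure = m.group("structure").strip()
        exclude = m.group("exclude").strip() if m.group("exclude") else None
        exclude_margin = 0.0
        if exclude is not None and "+" in exclude:
            exclude, margin_txt = (part.strip() for part in exclude.split("+", 1))
            if not margin_txt.endswith("mm"):
                raise ValueError(f"bad exclusion margin {margin_txt!r} in {text!r}")
            exclude_margin = float(margin_txt[:-2])
        importance: Importance = m.group("importance") or "hard"
        body = m.group("body").strip()

        sp = cls._SPARING.match(body)
        if sp:
            return cls(
                structure,
                MetricSpec("sparing_cc", float(sp.group("d"))),
                float(sp.group("lim")),
                "lower",
                importance,
                score_weight,
                exclude,
                exclude_margin,
            )
        v = cls._V.match(body)
        if v:
            kind = "v_percent" if v.group("unit") == "%" else "v_cc"
            direction: Direction = "lower" if v.group("op") == ">" else "upper"
            return cls(
                structure,
                MetricSpec(kind, float(v.group("d"))),
                float(v.group("lim")),
                direction,
                importance,
                score_weight,
                exclude,
                exclude_margin,
            )
        s = cls._SCALAR.match(body)
        if s:
            return cls(
                structure,
                MetricSpec(s.group("kind")),
                float(s.group("lim")),
                "upper",
                importance,
                score_weight,
                exclude,
                exclude_margin,
            )
        raise ValueError(f"cannot parse constraint body {body!r} in {text!r}")

    def serialize(self) -> str:
        def num(x: float) -> str:
            return f"{x:g}"

        if self.exclude is None:
            name = self.structure
        elif self.exclude_margin_mm > 0:
            name = f"{self.structure} (-{self.exclude}+{self.exclude_margin_mm:g}mm)"
        else:
            name = f"{self.structure} (-{self.exclude})"
        k = self.metric.kind
        if k == "sparing_cc":
            body = f"Vtot-V{num(self.metric.dose_level)}Gy > {num(self.limit)} cc"
        elif k in ("v_percent", "v_cc"):
            op = ">" if self.direction == "lower" else "<"
            unit = "%" if k == "v_percent" else "cc"
            body = f"V{num(self.metric.dose_level)}Gy {op} {num(self.limit)} {unit}"
        else:
            body = f"{k} < {num(self.limit)}Gy"
        return f"{name}: {body} [{self.importance}]"

    def with_weight(self, score_weight: float) -> "ConstraintSpec":
        return replace(self, score_weight=score_weight)


# --------------------------------------------------------------------------
# built-in constraint sets (stereotactic abdomen, standard HN)

_ABDOMEN_ROWS = [
    "ctv: V47.5Gy > 95% [soft]",
    "stomach: V33Gy < 1 cc [hard]",
    "small_bowel: V33Gy < 1 cc [hard]",
    "large_bowel: V33Gy < 1 cc [hard]",
    "duodenum: V33Gy < 1 cc [hard]",
    "spinal_cord: V25Gy < 0.5 cc [hard]",
    "kidneys: mean < 10Gy [hard]",
    "liver: mean < 20Gy [hard]",
    "liver: Vtot-V15Gy > 700 cc [hard]",
]

_HN_ROWS = [
    "high_risk_ctv: V66.5Gy > 95% [hard]",
    "high_risk_ctv: V74.9Gy < 1 cc [hard]",
    "low_risk_ctv: V51.3Gy > 95% [hard]",
    "low_risk_ctv (-high_risk_ctv+10mm): V57.8Gy < 1 cc [soft]",
    "brainstem: max < 54Gy [hard]",
    "spinal_cord: max < 45Gy [hard]",
    "constrictors: mean < 42Gy [hard]",
    "larynx: mean < 40Gy [hard]",
    "parotids: mean < 26Gy [hard]",
]


def constraint_table(template: str) -> list[ConstraintSpec]:
    """The clinical constraint list for a phantom template."""
    if template == "abdomen":
        rows = _ABDOMEN_ROWS
    elif template == "head_neck":
        rows = _HN_ROWS
    else:
        raise ValueError(f"no constraint table for template {template!r}")
    return [ConstraintSpec.parse(r) for r in rows]


# --------------------------------------------------------------------------
# file I/O


def to_yaml(constraints: Sequence[ConstraintSpec]) -> str:
    return yaml.safe_dump(
        {"constraints": [{"rule": c.serialize(), "score_weight": c.score_weight} for c in constraints]},
        sort_keys=False,
    )


def from_yaml(text: str) -> list[ConstraintSpec]:
    data = yaml.safe_load(text)
    out = []
    for entry in data["constraints"]:
        if isinstance(entry, str):
            out.append(ConstraintSpec.parse(entry))
        else:
            out.append(ConstraintSpec.parse(entry["rule"], float(entry.get("score_weight", 1.0))))
    return out


def to_csv(constraints: Sequence[ConstraintSpec]) -> str:
    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(["structure", "rule", "importance", "score_weight"])
    for c in constraints:
        w.writerow([c.structure, c.serialize(), c.importance, c.score_weight])
    return buf.getvalue()
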