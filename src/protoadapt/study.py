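"""Config-driven comparative study on a synthetic cohort.

One study run generates, per template, a small cohort of planning
phantoms; for each phantom it optimizes an initial robust plan, then
for each fraction generates the daily anatomy, simulates the
DIR-propagated contour ensembles, re-optimizes with every requested
adaptation strategy, and scores all resulting doses on the daily
clinical structures.  Scores are differenced against the reference
adaptation of the same fraction and aggregated per strategy.

All randomness flows through seeds derived deterministically from the
config seed, so a rerun reproduces the result tables bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constraints import ConstraintSpec, constraint_table, from_yaml as constraints_from_yaml
from .dirsim import DirNoiseModel, simulate_dir_sets
from .dose import BeamConfig, build_scenario_influences, compute_dose, place_spots, scenario_set
from .evaluation import ScoreReport, aggregate, score, score_difference, sensitivity_analysis
from .objectives import ObjectiveConfig
from .phantoms import AnatomyChangeModel, Phantom, PhantomSpec, default_geometry, generate_fraction, generate_phantom
from .planning import Plan, SolverConfig, build_strategy_problem, optimize_initial_plan

log = logging.getLogger("protoadapt")

DEFAULT_STRATEGIES = (
    "reference",
    "single_dir_1",
    "single_dir_2",
    "single_dir_3",
    "multi_dir",
    "conservative",
    "probabilistic",
    "no_adaptation",
)


@dataclass(frozen=True)
class Prescription:
    """Per-template prescription and beam arrangement."""

    rx_gy: float
    n_fractions: int
    beam_directions: tuple[tuple[float, float, float], ...]
    coverage_level_gy: float  # target coverage threshold (Table rows)
    spot_lateral_spacing_mm: float = 7.0
    range_layer_spacing_mm: float = 6.0

    def make_beams(self) -> list[BeamConfig]:
        return [
            BeamConfig(
                direction=d,
                spot_lateral_spacing_mm=self.spot_lateral_spacing_mm,
                range_layer_spacing_mm=self.range_layer_spacing_mm,
            )
            for d in self.beam_directions
        ]


# 3-beam posterior/oblique arrangement for the stereotactic abdomen,
# 4 anterior-oblique beams for head & neck (sparing brainstem/cord
# distally, which is where protons stop).
DEFAULT_PRESCRIPTIONS = {
    "abdomen": Prescription(
        rx_gy=50.0,
        n_fractions=5,
        beam_directions=((0.0, -1.0, 0.0), (-0.643, -0.766, 0.0), (0.643, -0.766, 0.0)),
        coverage_level_gy=47.5,
    ),
    "head_neck": Prescription(
        rx_gy=70.0,
        n_fractions=30,
        beam_directions=(
            (0.342, 0.940, 0.0),
            (-0.342, 0.940, 0.0),
            (0.766, 0.643, 0.0),
            (-0.766, 0.643, 0.0),
        ),
        coverage_level_gy=66.5,
        spot_lateral_spacing_mm=10.0,
        range_layer_spacing_mm=9.0,
    ),
}

DEFAULT_ANATOMY_CHANGE = {
    "abdomen": {"rigid_shift_sd_mm": 2.0, "organ_displacement_amp_mm": 6.0,
                "target_volume_scale": 1.0, "external_shrink_fraction": 0.0},
    "head_neck": {"rigid_shift_sd_mm": 1.5, "organ_displacement_amp_mm": 4.0,
                  "target_volume_scale": 1.0, "external_shrink_fraction": 0.08},
}

# Contour-propagation error magnitudes per site: abdominal soft-tissue
# registration errs more than head & neck, which is anchored by bone.
DEFAULT_DIR_NOISE = {
    "abdomen": {
        "n_algorithms": 3,
        "bias_amp_mm": 3.5,
        "random_amp_mm": 2.0,
        "correlation_length_mm": 25.0,
        "target_dice_band": (0.5, 1.0),
    },
    "head_neck": {
        "n_algorithms": 3,
        "bias_amp_mm": 2.0,
        "random_amp_mm": 1.2,
        "correlation_length_mm": 25.0,
        "target_dice_band": (0.6, 1.0),
    },
}


@dataclass
class StudyConfig:
    """Full recipe for one comparative study."""

    seed: int = 1234
    templates: tuple[str, ...] = ("abdomen", "head_neck")
    n_phantoms: int = 3
    n_fractions: int = 3
    strategies: tuple[str, ...] = DEFAULT_STRATEGIES
    dir_noise: dict = dc_field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DIR_NOISE.items()})
    anatomy_change: dict = dc_field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ANATOMY_CHANGE.items()})
    setup_uncertainty_mm: float = 3.0
    range_uncertainty: float = 0.03
    solver: SolverConfig = dc_field(default_factory=SolverConfig)
    hard_weight: float = 10.0
    soft_weight: float = 1.0
    phantom_jitter_mm: float = 3.0
    constraint_files: dict = dc_field(default_factory=dict)  # template -> yaml path
    output_dir: str | None = None

    # ---- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["solver"] = dataclasses.asdict(self.solver)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "solver" in d and isinstance(d["solver"], dict):
            solver = dict(d["solver"])
            if "gap_schedule" in solver:
                solver["gap_schedule"] = tuple(solver["gap_schedule"])
            d["solver"] = SolverConfig(**solver)
        for key in ("templates", "strategies"):
            if key in d:
                d[key] = tuple(d[key])
        if "dir_noise" in d:
            dn = {k: (dict(v) if isinstance(v, dict) else v) for k, v in d["dir_noise"].items()}
            for v in dn.values():
                if isinstance(v, dict) and "target_dice_band" in v:
                    v["target_dice_band"] = tuple(v["target_dice_band"])
            if "target_dice_band" in dn and not isinstance(dn["target_dice_band"], dict):
                dn["target_dice_band"] = tuple(dn["target_dice_band"])
            d["dir_noise"] = dn
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:12]

    def dir_noise_for(self, template: str) -> dict:
        """Noise parameters for a template (flat dicts apply to all)."""
        if template in self.dir_noise:
            return dict(self.dir_noise[template])
        return dict(self.dir_noise)

    def constraints_for(self, template: str) -> list[ConstraintSpec]:
        if template in self.constraint_files:
            return constraints_from_yaml(Path(self.constraint_files[template]).read_text())
        return constraint_table(template)


def _phantom_seed(config_seed: int, template: str, phantom_idx: int) -> int:
    h = hashlib.sha256(f"{config_seed}:{template}:{phantom_idx}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class CaseArtifacts:
    """Everything computed once per phantom (shared by its fractions)."""

    planning: Phantom
    spots: object
    planning_influences: list
    initial_plan: Plan
    constraints: list[ConstraintSpec]
    prescription: Prescription
    objective_config: ObjectiveConfig


def prepare_case(config: StudyConfig, template: str, phantom_idx: int) -> CaseArtifacts:
    """Generate a planning phantom and optimize its initial robust plan."""
    pseed = _phantom_seed(config.seed, template, phantom_idx)
    geometry = default_geometry(template, seed=pseed, jitter_mm=config.phantom_jitter_mm)
    spec = PhantomSpec(template=template, organ_geometry=geometry, seed=pseed)
    planning = generate_phantom(spec)
    rx = DEFAULT_PRESCRIPTIONS[template]
    constraints = config.constraints_for(template)
    spots = place_spots(planning, rx.make_beams())
    scenarios = scenario_set(config.setup_uncertainty_mm, config.range_uncertainty)
    influences = build_scenario_influences(planning, spots, scenarios)
    obj_cfg = ObjectiveConfig(
        hard_weight=config.hard_weight,
        soft_weight=config.soft_weight,
    )
    initial = optimize_initial_plan(
        planning, constraints, influences, obj_cfg, config.solver, rx.n_fractions
    )
    return CaseArtifacts(planning, spots, influences, initial, constraints, rx, obj_cfg)


def run_fraction(
    config: StudyConfig,
    case: CaseArtifacts,
    template: str,
    phantom_idx: int,
    fraction_idx: int,
) -> tuple[dict[str, ScoreReport], Phantom]:
    """Run all requested strategies for one fraction; returns score reports."""
    pseed = _phantom_seed(config.seed, template, phantom_idx)
    change = AnatomyChangeModel(seed=pseed, **config.anatomy_change[template])
    daily = generate_fraction(case.planning, change, fraction_idx)
    noise = DirNoiseModel(seed=(pseed * 7 + fraction_idx) % (2**31), **config.dir_noise_for(template))
    dir_sets = simulate_dir_sets(daily, noise)

    scenarios = scenario_set(config.setup_uncertainty_mm, config.range_uncertainty)
    influences = build_scenario_influences(daily, case.spots, scenarios)
    nominal = influences[0]
    n_fx = case.prescription.n_fractions

    strategies = list(config.strategies)
    if "reference" not in strategies:
        strategies = ["reference"] + strategies

    reports: dict[str, ScoreReport] = {}
    for strat in strategies:
        built = build_strategy_problem(
            strat,
            dir_sets,
            daily.clinical_structures,
            case.constraints,
            influences,
            case.initial_plan,
            case.objective_config,
            n_fx,
        )
        if isinstance(built, Plan):
            plan = built
        else:
            from .planning import solve

            plan = solve(
                built,
                config.solver,
                initial_weights=case.initial_plan.weights,
                strategy=strat,
            )
        dose = compute_dose(nominal, plan.weights, n_fx)
        reports[strat] = score(
            dose, daily.clinical_structures, case.constraints, strat, fraction_idx
        )
    return reports, daily


def run_study(config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full comparative study.

    Returns ``(records, contributions)``: per-(template, phantom,
    fraction, strategy) total scores and score differences, and the long
    per-constraint contribution table used by the sensitivity analysis.
    Failed fractions are logged and tabulated, not fatal.
    """
    records = []
    contributions = []
    failures = []
    for template in config.templates:
        for p in range(config.n_phantoms):
            try:
                case = prepare_case(config, template, p)
            except Exception as exc:  # pragma: no cover - defensive
                log.error("case %s/%d failed: %s", template, p, exc)
                failures.append((template, p, None, str(exc)))
                continue
            for f in range(1, config.n_fractions + 1):
                try:
                    reports, daily = run_fraction(config, case, template, p, f)
                except Exception as exc:
                    log.error("fraction %s/%d/%d failed: %s", template, p, f, exc)
                    failures.append((template, p, f, str(exc)))
                    continue
                ref = reports["reference"]
                roles = {
                    name: s.role
                    for name, s in daily.clinical_structures.structures.items()
                }
                for strat, rep in reports.items():
                    records.append(
                        {
                            "template": template,
                            "phantom": p,
                            "fraction": f,
                            "strategy": strat,
                            "score": rep.total,
                            "score_diff": score_difference(rep, ref),
                            "n_violated": rep.n_violated,
                        }
                    )
                    for r in rep.results:
                        contributions.append(
                            {
                                "template": template,
                                "phantom": p,
                                "fraction": f,
                                "strategy": strat,
                                "constraint": r.spec.serialize(),
                                "structure_role": roles[r.spec.structure],
                                "value": r.value,
                                "contribution_au": r.contribution,
                            }
                        )
    records_df = pd.DataFrame(records)
    contributions_df = pd.DataFrame(contributions)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        records_df.to_csv(out / "scores.csv", index=False)
        contributions_df.to_csv(out / "contributions.csv", index=False)
        if len(records_df):
            aggregate(records_df).summary.to_csv(out / "summary.csv", index=False)
        meta = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "failures": failures,
        }
        (out / "study_manifest.json").write_text(json.dumps(meta, indent=1))
    return records_df, contributions_df


def make_report(records: pd.DataFrame, contributions: pd.DataFrame, out_dir: str | None = None):
    """Aggregate a finished study and run the weight-sensitivity sweep."""
    table = aggregate(records)
    sens = sensitivity_analysis(contributions) if len(contributions) else None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.summary.to_csv(out / "summary.csv", index=False)
        if sens is not None:
            sens.table.to_csv(out / "sensitivity.csv", index=False)
        _plot_summary(table.summary, out / "score_differences.png")
    return table, sens


def _plot_summary(summary: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        1, summary["template"].nunique(), figsize=(5 * summary["template"].nunique(), 4),
        squeeze=False,
    )
    for ax, (template, grp) in zip(axes[0], summary.groupby("template")):
        grp = grp.sort_values("mean")
        x = np.arange(len(grp))
        mean = grp["mean"].to_numpy()
        ax.errorbar(
            x,
            mean,
            yerr=[mean - grp["min"].to_numpy(), grp["max"].to_numpy() - mean],
            fmt="o",
            capsize=4,
        )
        ax.set_xticks(x)
        ax.set_xticklabels(grp["strategy"], rotation=45, ha="right")
        ax.set_ylabel("score difference to reference (au)")
        ax.set_title(template)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
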