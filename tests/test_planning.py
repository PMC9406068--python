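"""Minimax solver and the six adaptation strategies, on toy problems."""

import numpy as np
import pytest
from scipy import sparse

from protoadapt.constraints import ConstraintSpec
from protoadapt.dose import InfluenceMatrix, Scenario
from protoadapt.grids import Grid
from protoadapt.objectives import ObjectiveConfig, build_composite
from protoadapt.planning import (
    Plan,
    RobustProblem,
    SolverConfig,
    build_strategy_problem,
    solve,
    worst_objective,
)
from protoadapt.structures import Structure, StructureSet


def _toy_problem(seed=0, n_spots=2, n_cells=8, duplicate_pairs=1):
    """Tiny problem: a few spots covering a 2x2x2 grid with one target/one OAR."""
    rng = np.random.default_rng(seed)
    grid = Grid((2, 2, 2), (10.0, 10.0, 10.0))
    target = np.zeros(grid.shape, bool)
    target.ravel()[:4] = True
    oar = np.zeros(grid.shape, bool)
    oar.ravel()[4:] = True
    sset = StructureSet(grid, {"t": Structure(target, "target"), "o": Structure(oar, "oar")})
    constraints = [
        ConstraintSpec.parse("t: V9Gy > 95% [hard]"),
        ConstraintSpec.parse("o: mean < 4Gy [hard]"),
    ]
    comp = build_composite(constraints, sset, ObjectiveConfig())
    mat = sparse.csr_matrix(rng.random((n_spots, grid.n_voxels)))
    inf = InfluenceMatrix(mat, grid, Scenario())
    pairs = [(comp, inf)] * duplicate_pairs
    init_idx = np.nonzero(target.ravel())[0]
    return RobustProblem(list(pairs), 1, init_idx, 10.0), sset, constraints


class TestSolve:
    def test_single_pair_reduces_objective(self):
        problem, _, _ = _toy_problem()
        w0 = np.full(problem.n_spots, 0.1)
        before = worst_objective(problem, w0)
        plan = solve(problem, SolverConfig(), initial_weights=w0)
        assert plan.diagnostics["final_worst_objective"] <= before
        assert (plan.weights >= 0).all()

    def test_duplicated_pairs_match_single_pair_solution(self):
        single, _, _ = _toy_problem(duplicate_pairs=1)
        triple, _, _ = _toy_problem(duplicate_pairs=3)
        a = solve(single, SolverConfig())
        b = solve(triple, SolverConfig())
        fa = worst_objective(single, a.weights)
        fb = worst_objective(single, b.weights)
        assert fb <= fa * 1.02 + 1e-9

    def test_two_spot_toy_matches_grid_search(self):
        """Brute-force over the weight grid: minimax objective within 2%."""
        problem, _, _ = _toy_problem(seed=3)
        plan = solve(problem, SolverConfig())
        best = np.inf
        for w1 in np.linspace(0.0, 20.0, 201):
            for w2 in np.linspace(0.0, 20.0, 201):
                best = min(best, worst_objective(problem, np.array([w1, w2])))
        achieved = worst_objective(problem, plan.weights)
        assert achieved <= best * 1.02 + 1e-6

    def test_solve_is_deterministic(self):
        problem, _, _ = _toy_problem(seed=5)
        a = solve(problem, SolverConfig())
        b = solve(problem, SolverConfig())
        assert np.array_equal(a.weights, b.weights)

    def test_objective_monotone_within_each_round(self):
        problem, _, _ = _toy_problem(seed=7)
        plan = solve(problem, SolverConfig())
        for round_hist in plan.diagnostics["objective_history"]:
            # L-BFGS-B evaluates trial points during line search; the
            # running minimum over evaluations must reach the final value
            running = np.minimum.accumulate(round_hist)
            assert running[-1] <= round_hist[0] + 1e-12

    def test_minimax_dominance_over_scenarios(self):
        """The robust plan's worst case beats single-scenario plans' worst case."""
        rng = np.random.default_rng(11)
        grid = Grid((2, 2, 2), (10.0, 10.0, 10.0))
        target = np.zeros(grid.shape, bool)
        target.ravel()[:4] = True
        sset = StructureSet(grid, {"t": Structure(target, "target")})
        constraints = [ConstraintSpec.parse("t: V9Gy > 95% [hard]")]
        comp = build_composite(constraints, sset, ObjectiveConfig())
        infs = [
            InfluenceMatrix(sparse.csr_matrix(rng.random((3, grid.n_voxels))), grid, Scenario())
            for _ in range(3)
        ]
        init_idx = np.nonzero(target.ravel())[0]
        robust = RobustProblem([(comp, i) for i in infs], 1, init_idx, 10.0)
        robust_plan = solve(robust, SolverConfig())
        robust_worst = worst_objective(robust, robust_plan.weights)
        for inf in infs:
            single = RobustProblem([(comp, inf)], 1, init_idx, 10.0)
            single_plan = solve(single, SolverConfig())
            assert robust_worst <= worst_objective(robust, single_plan.weights) * 1.01 + 1e-9


class TestStrategyProblems:
    def _inputs(self, seed=0):
        rng = np.random.default_rng(seed)
        grid = Grid((8, 8, 8), (4.0, 4.0, 4.0))

        def sset(shift):
            t = np.zeros(grid.shape, bool)
            t[2 + shift : 5 + shift, 2:5, 2:5] = True
            o = np.zeros(grid.shape, bool)
            o[6:8, 2:5, 2:5] = True
            return StructureSet(grid, {"t": Structure(t, "target"), "o": Structure(o, "oar")})

        clinical = sset(0)
        dir_sets = [sset(0), sset(1), sset(0)]
        constraints = [
            ConstraintSpec.parse("t: V9Gy > 95% [hard]"),
            ConstraintSpec.parse("o: mean < 4Gy [hard]"),
        ]
        infs = [
            InfluenceMatrix(
                sparse.csr_matrix(rng.random((6, grid.n_voxels))), grid, Scenario()
            )
            for _ in range(2)
        ]
        return dir_sets, clinical, constraints, infs

    def test_single_dir_uses_one_structure_set(self):
        dir_sets, clinical, constraints, infs = self._inputs()
        prob = build_strategy_problem(
            "single_dir_2", dir_sets, clinical, constraints, infs, None, ObjectiveConfig(), 1
        )
        assert isinstance(prob, RobustProblem)
        assert len(prob.pairs) == len(infs)  # one objective x scenarios

    def test_multi_dir_crosses_sets_and_scenarios(self):
        dir_sets, clinical, constraints, infs = self._inputs()
        prob = build_strategy_problem(
            "multi_dir", dir_sets, clinical, constraints, infs, None, ObjectiveConfig(), 1
        )
        assert len(prob.pairs) == len(dir_sets) * len(infs)

    def test_probabilistic_level_weights_are_k_over_K(self):
        dir_sets, clinical, constraints, infs = self._inputs()
        prob = build_strategy_problem(
            "probabilistic", dir_sets, clinical, constraints, infs, None, ObjectiveConfig(), 1
        )
        comp = prob.pairs[0][0]
        target_cov = [
            bt for bt in comp.terms if bt.term.structure == "t" and bt.term.kind == "dvh_lower"
        ]
        base = 10.0  # hard weight
        fracs = sorted(round(bt.weight / base, 4) for bt in target_cov)
        assert fracs == sorted(
            round(f, 4) for f in (1 / 3, 2 / 3, 1.0)[: len(fracs)]
        )

    def test_multi_dir_with_identical_sets_equals_single_dir(self):
        dir_sets, clinical, constraints, infs = self._inputs()
        same = [dir_sets[0]] * 3
        multi = build_strategy_problem(
            "multi_dir", same, clinical, constraints, infs, None, ObjectiveConfig(), 1
        )
        single = build_strategy_problem(
            "single_dir_1", same, clinical, constraints, infs, None, ObjectiveConfig(), 1
        )
        pm = solve(multi, SolverConfig())
        ps = solve(single, SolverConfig())
        assert worst_objective(single, pm.weights) <= worst_objective(
            single, ps.weights
        ) * 1.02 + 1e-9

    def test_no_adaptation_passes_weights_through(self):
        dir_sets, clinical, constraints, infs = self._inputs()
        initial = Plan(np.arange(6, dtype=float), "initial")
        out = build_strategy_problem(
            "no_adaptation", dir_sets, clinical, constraints, infs, initial, ObjectiveConfig(), 1
        )
        assert isinstance(out, Plan)
        assert np.array_equal(out.weights, initial.weights)
        assert out.strategy == "no_adaptation"

    def test_conservative_respects_priority_mode(self):
        dir_sets, clinical, constraints, infs = self._inputs()
        for mode in ("stereotactic", "coverage"):
            for s in dir_sets:
                s.priority_mode = mode
            clinical.priority_mode = mode
            prob = build_strategy_problem(
                "conservative", dir_sets, clinical, constraints, infs, None, ObjectiveConfig(), 1
            )
            comp = prob.pairs[0][0]
            t_term = [bt for bt in comp.terms if bt.term.structure == "t"][0]
            n_vox = len(t_term.mask_indices)
            sizes = [int(s["t"].mask.sum()) for s in dir_sets]
            if mode == "stereotactic":
                assert n_vox <= min(sizes)  # intersection
            else:
                assert n_vox >= max(sizes)  # union

    def test_unknown_strategy_rejected(self):
        dir_sets, clinical, constraints, infs = self._inputs()
        with pytest.raises(ValueError, match="strategy"):
            build_strategy_problem(
                "mystery", dir_sets, clinical, constraints, infs, None, ObjectiveConfig(), 1
            )

    def test_all_strategies_share_the_constraint_list(self):
        """Only structure sets and weights differ between strategies."""
        dir_sets, clinical, constraints, infs = self._inputs()
        kinds = {}
        for tag in ("single_dir_1", "multi_dir", "conservative", "probabilistic", "reference"):
            prob = build_strategy_problem(
                tag, dir_sets, clinical, constraints, infs, None, ObjectiveConfig(), 1
            )
            comp = prob.pairs[0][0]
            kinds[tag] = sorted({(bt.term.structure, bt.term.kind, bt.term.dose_level)
                                 for bt in comp.terms})
        assert len({tuple(v) for v in kinds.values()}) == 1


def test_plan_json_round_trip():
    plan = Plan(np.array([0.5, 1.5, 0.0]), "reference", {"iterations": 12, "converged": True})
    again = Plan.from_json(plan.to_json())
    assert np.array_equal(again.weights, plan.weights)
    assert again.strategy == plan.strategy
    assert again.diagnostics["iterations"] == 12


def test_negative_weights_rejected():
    with pytest.raises(ValueError):
        Plan(np.array([-0.1, 1.0]), "reference")
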