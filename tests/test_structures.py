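"""Contour-ensemble algebra, volumes, DVH metrics — against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protoadapt.grids import Grid
from protoadapt.structures import (
    AgreementMap,
    MetricSpec,
    agreement_map,
    conservative_combination,
    dice,
    dose_metric,
    dvh_curve,
    intersection,
    level_fraction,
    substructure_partition,
    union,
    volume_cc,
)

from conftest import simple_structure_set


def _random_masks(seed, n=3, shape=(16, 16, 16), p=0.3):
    rng = np.random.default_rng(seed)
    return [rng.random(shape) < p for _ in range(n)]


class TestUnionIntersection:
    def test_idempotent_on_identical_masks(self):
        m = _random_masks(0, n=1)[0]
        assert np.array_equal(union([m, m, m]), m)
        assert np.array_equal(intersection([m, m, m]), m)

    def test_disjoint_masks(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[:2], b[6:] = True, True
        assert union([a, b]).sum() == a.sum() + b.sum()
        assert not intersection([a, b]).any()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_voxelwise_oracle(self, seed):
        masks = _random_masks(seed)
        ref_or = masks[0] | masks[1] | masks[2]
        ref_and = masks[0] & masks[1] & masks[2]
        assert np.array_equal(union(masks), ref_or)
        assert np.array_equal(intersection(masks), ref_and)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            union([np.zeros((4, 4, 4), bool), np.zeros((5, 4, 4), bool)])
        with pytest.raises(ValueError):
            union([])

    def test_containment_invariant(self):
        masks = _random_masks(11)
        u, i = union(masks), intersection(masks)
        for m in masks:
            assert (i <= m).all() and (m <= u).all()


class TestAgreementAndSubstructures:
    def _ensemble(self, masks, grid=None):
        grid = grid or Grid((16, 16, 16), (2.0, 2.0, 2.0))
        return [
            simple_structure_set(grid, {"t": (m, "target")}) for m in masks
        ]

    def test_agreement_values_are_counts_over_k(self):
        masks = _random_masks(1)
        amap = agreement_map(self._ensemble(masks))
        frac = amap.fraction("t")
        expected = (masks[0].astype(float) + masks[1] + masks[2]) / 3.0
        assert np.allclose(frac, expected)
        # 1 exactly on the intersection, > 0 exactly on the union
        assert np.array_equal(frac == 1.0, intersection(masks))
        assert np.array_equal(frac > 0.0, union(masks))

    def test_voxel_in_two_of_three_goes_to_level_67_only(self):
        grid = Grid((16, 16, 16), (2.0, 2.0, 2.0))
        masks = [np.zeros(grid.shape, bool) for _ in range(3)]
        masks[0][8, 8, 8] = True
        masks[1][8, 8, 8] = True  # exactly two of three
        masks[2][4, 4, 4] = True  # exactly one of three
        parts = substructure_partition(agreement_map(self._ensemble(masks, grid)))
        assert parts.levels["t"][67][8, 8, 8]
        assert not parts.levels["t"][100][8, 8, 8]
        assert not parts.levels["t"][33][8, 8, 8]
        assert parts.levels["t"][33][4, 4, 4]

    def test_levels_partition_the_union(self):
        masks = _random_masks(2)
        parts = substructure_partition(agreement_map(self._ensemble(masks)))
        levels = list(parts.levels["t"].values())
        assert set(parts.levels["t"]) == {33, 67, 100}
        total = np.zeros_like(levels[0], dtype=int)
        for m in levels:
            total += m
        assert total.max() <= 1  # pairwise disjoint
        assert np.array_equal(total > 0, union(masks))

    def test_level_fraction_inverts_labels(self):
        assert level_fraction(67, 3) == pytest.approx(2 / 3)
        assert level_fraction(33, 3) == pytest.approx(1 / 3)
        assert level_fraction(100, 3) == 1.0
        with pytest.raises(ValueError):
            level_fraction(50, 3)

    def test_roster_mismatch_is_reported(self):
        grid = Grid((8, 8, 8), (2.0, 2.0, 2.0))
        a = simple_structure_set(grid, {"t": (np.ones(grid.shape, bool), "target")})
        b = simple_structure_set(
            grid,
            {"t": (np.ones(grid.shape, bool), "target"),
             "oar": (np.ones(grid.shape, bool), "oar")},
        )
        with pytest.raises(ValueError, match="roster"):
            agreement_map([a, b])


class TestConservativeCombination:
    def _ensemble(self):
        grid = Grid((12, 12, 12), (2.0, 2.0, 2.0))
        rng = np.random.default_rng(5)
        sets = []
        for _ in range(3):
            sets.append(
                simple_structure_set(
                    grid,
                    {
                        "t": (rng.random(grid.shape) < 0.4, "target"),
                        "o": (rng.random(grid.shape) < 0.3, "oar"),
                    },
                )
            )
        return sets

    def test_stereotactic_mode_takes_target_intersection(self):
        sets = self._ensemble()
        combined = conservative_combination(sets, "stereotactic")
        assert np.array_equal(
            combined["t"].mask, intersection([s["t"].mask for s in sets])
        )
        assert np.array_equal(combined["o"].mask, union([s["o"].mask for s in sets]))

    def test_coverage_mode_takes_target_union(self):
        sets = self._ensemble()
        combined = conservative_combination(sets, "coverage")
        assert np.array_equal(combined["t"].mask, union([s["t"].mask for s in sets]))
        assert np.array_equal(combined["o"].mask, union([s["o"].mask for s in sets]))

    def test_identical_sets_collapse_to_common_set(self):
        grid = Grid((10, 10, 10), (2.0, 2.0, 2.0))
        rng = np.random.default_rng(8)
        masks = {"t": (rng.random(grid.shape) < 0.4, "target")}
        sets = [simple_structure_set(grid, masks) for _ in range(3)]
        for mode in ("stereotactic", "coverage"):
            combined = conservative_combination(sets, mode)
            assert np.array_equal(combined["t"].mask, masks["t"][0])

    def test_empty_target_intersection_flags_warning(self):
        grid = Grid((8, 8, 8), (2.0, 2.0, 2.0))
        a = np.zeros(grid.shape, bool); a[:2] = True
        b = np.zeros(grid.shape, bool); b[6:] = True
        sets = [
            simple_structure_set(grid, {"t": (m, "target")}) for m in (a, b)
        ]
        combined = conservative_combination(sets, "stereotactic")
        assert combined.warnings
        assert not combined["t"].mask.any()


class TestVolumesAndMetrics:
    def test_volume_arithmetic(self):
        grid = Grid((10, 10, 10), (2.0, 2.0, 2.0))
        mask = np.zeros(grid.shape, bool)
        mask.ravel()[:1000] = True
        assert volume_cc(mask, grid) == pytest.approx(8.0)
        assert volume_cc(np.zeros(grid.shape, bool), grid) == 0.0

    def test_uniform_dose_metrics(self):
        grid = Grid((10, 10, 10), (2.0, 2.0, 2.0))
        mask = np.zeros(grid.shape, bool)
        mask.ravel()[:1000] = True  # 8 cc
        dose = np.full(grid.shape, 50.0)
        assert dose_metric(dose, mask, MetricSpec("v_percent", 47.5), grid) == 100.0
        assert dose_metric(dose, mask, MetricSpec("v_cc", 33.0), grid) == pytest.approx(8.0)
        assert dose_metric(dose, mask, MetricSpec("mean"), grid) == 50.0
        assert dose_metric(dose, mask, MetricSpec("max"), grid) == 50.0
        assert dose_metric(dose, mask, MetricSpec("sparing_cc", 15.0), grid) == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_metrics_match_voxel_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = Grid((16, 16, 16), (2.0, 2.5, 3.0))
        mask = rng.random(grid.shape) < 0.4
        dose = rng.random(grid.shape) * 60.0
        d, lvl = dose[mask], 30.0
        vox_cc = grid.voxel_volume_mm3 / 1000.0
        assert dose_metric(dose, mask, MetricSpec("v_percent", lvl), grid) == pytest.approx(
            100.0 * (d >= lvl).sum() / mask.sum()
        )
        assert dose_metric(dose, mask, MetricSpec("v_cc", lvl), grid) == pytest.approx(
            (d >= lvl).sum() * vox_cc
        )
        assert dose_metric(dose, mask, MetricSpec("sparing_cc", lvl), grid) == pytest.approx(
            (d < lvl).sum() * vox_cc
        )
        assert dose_metric(dose, mask, MetricSpec("mean"), grid) == pytest.approx(d.mean())
        assert dose_metric(dose, mask, MetricSpec("max"), grid) == pytest.approx(d.max())

    def test_threshold_is_inclusive(self):
        grid = Grid((4, 4, 4), (2.0, 2.0, 2.0))
        mask = np.ones(grid.shape, bool)
        dose = np.full(grid.shape, 33.0)
        # V(33) counts dose >= 33
        assert dose_metric(dose, mask, MetricSpec("v_percent", 33.0), grid) == 100.0

    def test_empty_mask_is_an_error(self, small_grid):
        with pytest.raises(ValueError):
            dose_metric(np.zeros(small_grid.shape), np.zeros(small_grid.shape, bool),
                        MetricSpec("mean"), small_grid)


class TestDvh:
    def test_uniform_dose_is_step_function(self):
        grid = Grid((8, 8, 8), (2.0, 2.0, 2.0))
        mask = np.ones(grid.shape, bool)
        levels, vol = dvh_curve(np.full(grid.shape, 20.0), mask, grid, bin_width_gy=1.0)
        assert vol[0] == 100.0
        assert np.all(vol[levels <= 20.0] == 100.0)
        assert np.all(vol[levels > 20.0] == 0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_and_consistent_with_v_metric(self, seed):
        rng = np.random.default_rng(seed)
        grid = Grid((12, 12, 12), (2.0, 2.0, 2.0))
        mask = rng.random(grid.shape) < 0.5
        dose = rng.random(grid.shape) * 40.0
        levels, vol = dvh_curve(dose, mask, grid, bin_width_gy=0.5)
        assert np.all(np.diff(vol) <= 1e-12)
        for lv in levels[:: max(1, len(levels) // 7)]:
            assert vol[np.searchsorted(levels, lv)] == pytest.approx(
                dose_metric(dose, mask, MetricSpec("v_percent", lv), grid)
            )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), p=st.floats(0.05, 0.9))
def test_set_algebra_properties(seed, p):
    """intersection ⊆ every mask ⊆ union; agreement bounds; dice symmetry."""
    rng = np.random.default_rng(seed)
    masks = [rng.random((8, 8, 8)) < p for _ in range(3)]
    u, i = union(masks), intersection(masks)
    for m in masks:
        assert not (i & ~m).any()
        assert not (m & ~u).any()
    assert dice(masks[0], masks[1]) == pytest.approx(dice(masks[1], masks[0]))
    assert 0.0 <= dice(masks[0], masks[1]) <= 1.0
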