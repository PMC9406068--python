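"""Dose engine: WED, depth-dose shape contract, spots, influence, scenarios."""

import numpy as np
import pytest

from protoadapt.dose import (
    BeamConfig,
    NOMINAL,
    Scenario,
    bragg_curve,
    build_influence,
    build_scenario_influences,
    compute_dose,
    place_spots,
    scenario_set,
    water_equivalent_depth,
)
from protoadapt.grids import Grid
from protoadapt.phantoms import Phantom
from protoadapt.structures import Structure, StructureSet

from conftest import sphere_mask


def uniform_phantom(density=1.0, shape=(40, 40, 40), spacing=3.0, target_radius=18.0):
    grid = Grid(shape, (spacing, spacing, spacing))
    target = sphere_mask(grid, grid.center_mm, target_radius)
    sset = StructureSet(grid, {"t": Structure(target, "target")})
    return Phantom(grid, np.full(grid.shape, density, dtype=np.float32), sset, "abdomen")


class TestWaterEquivalentDepth:
    def test_uniform_unit_density(self):
        p = uniform_phantom(1.0)
        s, wed = water_equivalent_depth(p, (0.0, 58.5, 58.5), (1.0, 0.0, 0.0))
        assert np.allclose(wed[1:], s[1:], rtol=0.02)

    def test_uniform_half_density(self):
        p = uniform_phantom(0.5)
        s, wed = water_equivalent_depth(p, (0.0, 58.5, 58.5), (1.0, 0.0, 0.0))
        k = np.searchsorted(s, 40.0)
        assert wed[k] == pytest.approx(0.5 * s[k], rel=0.03)

    def test_slab_phantom_matches_piecewise_oracle(self):
        grid = Grid((40, 20, 20), (2.0, 2.0, 2.0))
        density = np.ones(grid.shape, dtype=np.float32)
        density[10:20] = 0.25  # low-density slab from x=20mm to x=40mm
        target = np.zeros(grid.shape, bool)
        target[25:30, 8:12, 8:12] = True
        p = Phantom(grid, density, StructureSet(grid, {"t": Structure(target, "target")}), "abdomen")
        s, wed = water_equivalent_depth(p, (0.0, 19.0, 19.0), (1.0, 0.0, 0.0), step_mm=0.5)
        # hand-summed: rho=1 for 19mm (to first slab edge at x=19), 0.25 for 20mm, 1 after
        def oracle(depth):
            a = min(depth, 19.0)
            b = min(max(depth - 19.0, 0.0), 20.0)
            c = max(depth - 39.0, 0.0)
            return a + 0.25 * b + c
        for depth in (10.0, 25.0, 45.0, 60.0):
            k = np.searchsorted(s, depth)
            assert wed[k] == pytest.approx(oracle(s[k]), abs=0.9)

    def test_monotone_nondecreasing(self):
        p = uniform_phantom(1.0)
        _, wed = water_equivalent_depth(p, (0.0, 58.5, 58.5), (0.6, 0.8, 0.0))
        assert np.all(np.diff(wed) >= -1e-12)

    def test_ray_missing_grid_errors(self):
        p = uniform_phantom()
        with pytest.raises(ValueError, match="misses"):
            water_equivalent_depth(p, (-10.0, -10.0, -10.0), (0.0, 0.0, -1.0))


class TestBraggCurve:
    @pytest.mark.parametrize("R", [60.0, 100.0, 160.0])
    def test_shape_contract(self, R):
        wed = np.linspace(0.0, 1.3 * R, 6000)
        d = bragg_curve(wed, R)
        peak = d.max()
        argmax = wed[np.argmax(d)]
        assert abs(argmax - R) <= 0.02 * R
        entrance = d[0]
        assert 0.2 * peak <= entrance <= 0.6 * peak
        distal = d[wed >= 1.05 * R]
        assert distal.max() <= 0.01 * peak
        # single global maximum: no secondary peak above the entrance region
        assert np.all(np.diff(np.sign(np.diff(d))) >= -2)  # continuity sanity

    def test_value_beyond_110_percent_range(self):
        assert bragg_curve(110.0, 100.0) < 0.01 * bragg_curve(100.0, 100.0)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            bragg_curve(10.0, 0.0)


class TestPlaceSpots:
    def test_every_target_voxel_is_covered(self):
        p = uniform_phantom()
        beam = BeamConfig(direction=(1.0, 0.0, 0.0))
        spots = place_spots(p, [beam])
        from protoadapt.dose import BeamGeometry

        geom = BeamGeometry(p, beam)
        idx = np.argwhere(p.clinical_structures["t"].mask)
        pts = idx * np.asarray(p.grid.spacing_mm)
        pu, pv, _ = geom.beam_coords(pts)
        wed = geom.wed_at(pts)
        for k in range(len(idx)):
            lat_ok = np.maximum(
                np.abs(spots.lat_u - pu[k]), np.abs(spots.lat_v - pv[k])
            ) <= beam.spot_lateral_spacing_mm / 2 + 1e-9
            depth_ok = np.abs(spots.range_mm - wed[k]) <= beam.range_layer_spacing_mm + 1e-9
            assert np.any(lat_ok & depth_ok), f"voxel {idx[k]} uncovered"

    def test_duplicate_beam_doubles_spot_count(self):
        p = uniform_phantom()
        b = BeamConfig(direction=(1.0, 0.0, 0.0))
        one = place_spots(p, [b])
        two = place_spots(p, [b, b])
        assert two.n_spots == 2 * one.n_spots

    def test_margin_increases_spot_count(self):
        p = uniform_phantom()
        n0 = place_spots(p, [BeamConfig(direction=(1, 0, 0), target_margin_mm=0.0)]).n_spots
        n5 = place_spots(p, [BeamConfig(direction=(1, 0, 0), target_margin_mm=5.0)]).n_spots
        assert n5 >= n0

    def test_empty_target_errors(self):
        p = uniform_phantom()
        with pytest.raises(ValueError):
            place_spots(p, [BeamConfig(direction=(1, 0, 0))],
                        target_mask=np.zeros(p.grid.shape, bool))


class TestInfluence:
    def test_single_spot_peaks_at_bragg_position(self):
        p = uniform_phantom(1.0)
        beam = BeamConfig(direction=(1.0, 0.0, 0.0))
        spots = place_spots(p, [beam])
        # pick one central spot
        k = np.argmin(np.abs(spots.lat_u) + np.abs(spots.lat_v) + np.abs(spots.range_mm - 60.0))
        inf = build_influence(p, spots, NOMINAL)
        row = np.asarray(inf.matrix[k].todense()).ravel().reshape(p.grid.shape)
        peak_vox = np.unravel_index(np.argmax(row), p.grid.shape)
        peak_mm = np.asarray(peak_vox) * np.asarray(p.grid.spacing_mm)
        # unit density: bragg position is range_mm along x from grid entry
        assert abs(peak_mm[0] - spots.range_mm[k]) <= p.grid.spacing_mm[0] + 1e-6

    def test_nominal_scenario_equals_default_build(self):
        p = uniform_phantom()
        spots = place_spots(p, [BeamConfig(direction=(1, 0, 0))])
        a = build_influence(p, spots)
        b = build_influence(p, spots, Scenario())
        assert (a.matrix != b.matrix).nnz == 0

    def test_setup_shift_translates_dose(self):
        p = uniform_phantom(1.0)
        spots = place_spots(p, [BeamConfig(direction=(1, 0, 0))])
        h = p.grid.spacing_mm[1]
        nominal = build_influence(p, spots, NOMINAL)
        shifted = build_influence(p, spots, Scenario(setup_shift_mm=(0.0, h, 0.0)))
        w = np.ones(spots.n_spots)
        d0 = compute_dose(nominal, w)
        d1 = compute_dose(shifted, w)
        # dose evaluated at x + shift: shifting patient +h along y moves the
        # dose pattern one voxel towards -y
        interior = np.s_[5:-5, 5:-5, 5:-5]
        assert np.allclose(d1[interior], np.roll(d0, -1, axis=1)[interior], atol=1e-3 * d0.max())

    def test_range_scaling_moves_peak_proximally(self):
        p = uniform_phantom(1.0)
        spots = place_spots(p, [BeamConfig(direction=(1, 0, 0))])
        k = int(np.argmax(spots.range_mm))
        R = spots.range_mm[k]
        over = build_influence(p, spots, Scenario(range_scale=1.1))
        row = np.asarray(over.matrix[k].todense()).ravel().reshape(p.grid.shape)
        peak_x = np.unravel_index(np.argmax(row), p.grid.shape)[0] * p.grid.spacing_mm[0]
        assert peak_x == pytest.approx(R / 1.1, abs=1.5 * p.grid.spacing_mm[0])

    def test_all_entries_nonnegative_and_rows_nonempty(self):
        p = uniform_phantom()
        spots = place_spots(p, [BeamConfig(direction=(0.6, 0.8, 0.0))])
        inf = build_influence(p, spots)
        assert inf.matrix.nnz > 0
        assert (inf.matrix.data >= 0).all()
        rows_nnz = np.diff(inf.matrix.indptr)
        assert (rows_nnz > 0).all()


class TestComputeDose:
    def _toy(self):
        p = uniform_phantom(shape=(24, 24, 24), spacing=3.0, target_radius=10.0)
        spots = place_spots(p, [BeamConfig(direction=(1, 0, 0))])
        return p, spots, build_influence(p, spots)

    def test_zero_weights_zero_dose(self):
        _, spots, inf = self._toy()
        assert not compute_dose(inf, np.zeros(spots.n_spots)).any()

    def test_linearity(self):
        _, spots, inf = self._toy()
        rng = np.random.default_rng(0)
        w = rng.random(spots.n_spots)
        assert np.allclose(compute_dose(inf, 2 * w), 2 * compute_dose(inf, w))
        assert np.allclose(compute_dose(inf, w, n_fractions=5), 5 * compute_dose(inf, w))

    def test_matches_dense_matvec_oracle(self):
        _, spots, inf = self._toy()
        rng = np.random.default_rng(1)
        w = rng.random(spots.n_spots)
        dense = np.asarray(inf.matrix.todense())
        assert np.allclose(compute_dose(inf, w).ravel(), w @ dense)

    def test_negative_weights_rejected(self):
        _, spots, inf = self._toy()
        w = np.zeros(spots.n_spots)
        w[0] = -1.0
        with pytest.raises(ValueError):
            compute_dose(inf, w)


class TestScenarioSet:
    def test_default_is_nine_scenarios_with_nominal(self):
        scenarios = scenario_set()
        assert len(scenarios) == 9
        assert scenarios[0].label == "nominal"
        shifts = [s for s in scenarios if s.setup_shift_mm != (0.0, 0.0, 0.0)]
        assert len(shifts) == 6
        for s in shifts:
            assert np.linalg.norm(s.setup_shift_mm) == pytest.approx(3.0)
        scales = {s.range_scale for s in scenarios}
        assert scales == {1.0, 0.97, 1.03}

    def test_zero_magnitudes_collapse_to_nominal(self):
        assert len(scenario_set(0.0, 0.0)) == 1

    def test_cross_product_gives_21(self):
        assert len(scenario_set(cross_product=True)) == 21
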