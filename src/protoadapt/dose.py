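"""Simplified spot-scanning proton dose model.

A plan is a set of pencil-beam spots, each with a beam direction, a
lateral position in the beam frame and a nominal range in mm of water.
Per-spot dose is separable: an analytic depth-dose profile evaluated at
the voxel's water-equivalent depth (WED), times a lateral Gaussian
around the spot axis.  Spot-by-voxel doses are assembled into sparse
influence matrices, one per setup/range error scenario; plan dose is
then linear in the spot weights.

The depth-dose model is not a fitted Bragg parametrization; it is an
analytic profile engineered to have the qualitative features that drive
the study's logic: a single sharp maximum at the nominal range, a
30%-of-peak entrance plateau, and essentially no dose beyond 105% of
the range.  See the methods note for the exact form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, sparse
from scipy.special import expit

from .grids import Grid
from .phantoms import Phantom

# depth-dose shape constants (fractions of nominal range)
_PEAK_SIGMA_PROX = 0.05
_PEAK_SIGMA_DIST = 0.015
_PLATEAU_LEVEL = 0.30
_PLATEAU_OFFSET = 0.125
_PLATEAU_WIDTH = 0.012


@dataclass(frozen=True)
class BeamConfig:
    """Geometry and spot-placement parameters of one beam."""

    direction: tuple[float, float, float]
    spot_lateral_spacing_mm: float = 7.0
    range_layer_spacing_mm: float = 6.0
    lateral_sigma_mm: float = 5.0
    target_margin_mm: float = 5.0

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("beam direction must be non-zero")
        object.__setattr__(self, "direction", tuple(d / n))
        for v in (
            self.spot_lateral_spacing_mm,
            self.range_layer_spacing_mm,
            self.lateral_sigma_mm,
        ):
            if v <= 0:
                raise ValueError("beam spacings and sigma must be > 0")
        if self.target_margin_mm < 0:
            raise ValueError("target margin must be >= 0")

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal beam frame (u, v, d): two lateral axes + direction."""
        d = np.asarray(self.direction)
        a = np.zeros(3)
        a[int(np.argmin(np.abs(d)))] = 1.0
        u = np.cross(d, a)
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        return u, v, d


@dataclass(frozen=True)
class Scenario:
    """One setup/range error scenario."""

    setup_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    range_scale: float = 1.0
    label: str = "nominal"

    def __post_init__(self) -> None:
        if self.range_scale <= 0:
            raise ValueError("range_scale must be > 0")
        object.__setattr__(
            self, "setup_shift_mm", tuple(float(s) for s in self.setup_shift_mm)
        )


NOMINAL = Scenario()


def scenario_set(
    setup_magnitude_mm: float = 3.0,
    range_fraction: float = 0.03,
    cross_product: bool = False,
) -> list[Scenario]:
    """Error scenarios for robust optimization.

    Default: nominal + six axis-aligned setup shifts of the stated
    magnitude + two range scalings (1 ± range_fraction) = 9 scenarios.
    With ``cross_product=True``, all 7 shifts x 3 range scalings = 21.
    """
    if setup_magnitude_mm < 0 or range_fraction < 0:
        raise ValueError("scenario magnitudes must be >= 0")
    shifts: list[tuple[float, float, float]] = [(0.0, 0.0, 0.0)]
    if setup_magnitude_mm > 0:
        for ax in range(3):
            for sign in (+1.0, -1.0):
                s = [0.0, 0.0, 0.0]
                s[ax] = sign * setup_magnitude_mm
                shifts.append(tuple(s))
    scales = [1.0]
    if range_fraction > 0:
        scales += [1.0 - range_fraction, 1.0 + range_fraction]

    def lab(s, r):
        if s == (0.0, 0.0, 0.0) and r == 1.0:
            return "nominal"
        parts = []
        if s != (0.0, 0.0, 0.0):
            ax = int(np.argmax(np.abs(s)))
            parts.append(f"shift_{'xyz'[ax]}{'+' if s[ax] > 0 else '-'}")
        if r != 1.0:
            parts.append(f"range{r:g}")
        return "_".join(parts)

    if cross_product:
        return [Scenario(s, r, lab(s, r)) for s in shifts for r in scales]
    out = [NOMINAL]
    out += [Scenario(s, 1.0, lab(s, 1.0)) for s in shifts[1:]]
    out += [Scenario((0.0, 0.0, 0.0), r, lab((0.0, 0.0, 0.0), r)) for r in scales[1:]]
    return out


# --------------------------------------------------------------------------
# depth dose


def bragg_curve(wed_mm, nominal_range_mm: float):
    """Relative depth dose at water-equivalent depth ``wed_mm``.

    Single global maximum (~1.0) at the nominal range, an entrance
    plateau at 30% of peak, a wide proximal and sharp distal peak
    shoulder, and < 1% of peak beyond 1.05x the range.
    """
    R = float(nominal_range_mm)
    if R <= 0:
        raise ValueError("nominal_range must be > 0")
    wed = np.asarray(wed_mm, dtype=np.float64)
    delta = R - wed  # positive proximal of the peak
    sigma = np.where(delta >= 0, _PEAK_SIGMA_PROX * R, _PEAK_SIGMA_DIST * R)
    peak = np.exp(-(delta**2) / (2.0 * sigma**2))
    plateau = _PLATEAU_LEVEL * expit((delta - _PLATEAU_OFFSET * R) / (_PLATEAU_WIDTH * R))
    return peak + plateau


# --------------------------------------------------------------------------
# water-equivalent depth


def water_equivalent_depth(
    phantom: Phantom,
    entry_point_mm,
    direction,
    step_mm: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative WED profile along a single ray.

    Returns ``(s, wed)``: path length from the entry point and the
    water-equivalent depth at each sample.  Monotone non-decreasing; in
    uniform density rho, ``wed = rho * s``.  Errors if the ray never
    intersects the grid.
    """
    grid = phantom.grid
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("direction must be non-zero")
    d = d / n
    p0 = np.asarray(entry_point_mm, dtype=float)
    lo = np.asarray(grid.origin_mm)
    hi = lo + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing_mm)
    # slab intersection
    t0, t1 = -np.inf, np.inf
    for k in range(3):
        if d[k] == 0:
            if not (lo[k] - 1e-9 <= p0[k] <= hi[k] + 1e-9):
                raise ValueError("ray misses the grid")
            continue
        ta = (lo[k] - p0[k]) / d[k]
        tb = (hi[k] - p0[k]) / d[k]
        t0 = max(t0, min(ta, tb))
        t1 = min(t1, max(ta, tb))
    if t1 < max(t0, 0.0):
        raise ValueError("ray misses the grid")
    step = step_mm if step_mm is not None else min(grid.spacing_mm) / 2.0
    t_end = t1
    s = np.arange(0.0, t_end + step, step)
    mid = s[:-1] + step / 2.0
    pts = p0[None, :] + mid[:, None] * d[None, :]
    idx = grid.world_to_index(pts).T
    rho = ndimage.map_coordinates(
        phantom.density.astype(np.float64), idx, order=1, mode="constant", cval=0.0
    )
    wed = np.concatenate([[0.0], np.cumsum(rho * step)])
    return s, wed


class BeamGeometry:
    """Per-(phantom, beam) geometry: WED volume and lateral coordinates.

    The density is resampled onto a beam-aligned grid and integrated
    along the beam axis once; WED and lateral beam-frame coordinates of
    arbitrary world points are then cheap interpolations, which is how
    setup-shift scenarios are applied.
    """

    def __init__(self, phantom: Phantom, beam: BeamConfig, step_mm: float | None = None):
        self.beam = beam
        grid = phantom.grid
        self.iso = grid.center_mm
        self.u, self.v, self.d = beam.basis()
        h = step_mm if step_mm is not None else min(grid.spacing_mm)
        self.step = h
        # beam-frame extents: projections of the grid half-extent
        half = (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing_mm) / 2.0
        ext = np.stack([self.u, self.v, self.d])
        half_bf = np.abs(ext) @ half + h
        axes = [np.arange(-hb, hb + h, h) for hb in half_bf]
        self._bf_origin = np.array([a[0] for a in axes])
        AU, AV, AD = np.meshgrid(*axes, indexing="ij", sparse=True)
        # world positions of beam-frame samples
        px = self.iso[0] + AU * self.u[0] + AV * self.v[0] + AD * self.d[0]
        py = self.iso[1] + AU * self.u[1] + AV * self.v[1] + AD * self.d[1]
        pz = self.iso[2] + AU * self.u[2] + AV * self.v[2] + AD * self.d[2]
        shape_bf = (len(axes[0]), len(axes[1]), len(axes[2]))
        coords = np.empty((3, *shape_bf))
        sp = np.asarray(grid.spacing_mm)
        og = np.asarray(grid.origin_mm)
        coords[0] = (px - og[0]) / sp[0]
        coords[1] = (py - og[1]) / sp[1]
        coords[2] = (pz - og[2]) / sp[2]
        rho = ndimage.map_coordinates(
            phantom.density.astype(np.float64),
            coords.reshape(3, -1),
            order=1,
            mode="constant",
            cval=0.0,
        ).reshape(shape_bf)
        self.wed_bf = np.cumsum(rho, axis=2) * h

    def beam_coords(self, points_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        rel = points_mm - self.iso
        return rel @ self.u, rel @ self.v, rel @ self.d

    def wed_at(self, points_mm: np.ndarray) -> np.ndarray:
        pu, pv, pd = self.beam_coords(points_mm)
        coords = np.stack(
            [
                (pu - self._bf_origin[0]) / self.step,
                (pv - self._bf_origin[1]) / self.step,
                (pd - self._bf_origin[2]) / self.step,
            ]
        )
        return ndimage.map_coordinates(self.wed_bf, coords, order=1, mode="nearest")


# --------------------------------------------------------------------------
# spots


@dataclass
class SpotGrid:
    """Spot roster shared by all scenarios and strategies of one case."""

    beams: list[BeamConfig]
    beam_index: np.ndarray  # (n,)
    lat_u: np.ndarray  # (n,) mm in beam frame
    lat_v: np.ndarray
    range_mm: np.ndarray  # nominal range, mm water-equivalent

    @property
    def n_spots(self) -> int:
        return len(self.range_mm)


def _dilate_mm(mask: np.ndarray, grid: Grid, margin_mm: float) -> np.ndarray:
    if margin_mm <= 0:
        return mask
    dist = ndimage.distance_transform_edt(~mask, sampling=grid.spacing_mm)
    return dist <= margin_mm


def place_spots(
    phantom: Phantom,
    beams: Sequence[BeamConfig],
    target_mask: np.ndarray | None = None,
    geometries: dict[int, BeamGeometry] | None = None,
) -> SpotGrid:
    """Lay out spots so every target(+margin) voxel is covered.

    For each beam, target voxels are binned laterally at the beam's spot
    spacing; each occupied lateral cell receives energy layers spanning
    that cell's WED interval at the layer spacing.  By construction every
    target voxel lies within one lateral spacing and one layer spacing of
    some spot's Bragg position.
    """
    sset = phantom.clinical_structures
    if target_mask is None:
        target_mask = np.zeros(phantom.grid.shape, dtype=bool)
        for name in sset.targets():
            target_mask |= sset[name].mask
    if not target_mask.any():
        raise ValueError("cannot place spots on an empty target")

    bidx, lat_u, lat_v, rng_mm = [], [], [], []
    for b, beam in enumerate(beams):
        mask = _dilate_mm(target_mask, phantom.grid, beam.target_margin_mm)
        geom = (
            geometries[b]
            if geometries is not None and b in geometries
            else BeamGeometry(phantom, beam)
        )
        idx = np.argwhere(mask)
        pts = idx * np.asarray(phantom.grid.spacing_mm) + np.asarray(phantom.grid.origin_mm)
        pu, pv, _ = geom.beam_coords(pts)
        wed = geom.wed_at(pts)
        dl = beam.spot_lateral_spacing_mm
        iu = np.round(pu / dl).astype(int)
        iv = np.round(pv / dl).astype(int)
        cells: dict[tuple[int, int], list[int]] = {}
        for k, key in enumerate(zip(iu.tolist(), iv.tolist())):
            cells.setdefault(key, []).append(k)
        for (ci, cj), members in sorted(cells.items()):
            w = wed[members]
            wmin, wmax = float(w.min()), float(w.max())
            layers = np.arange(wmin, wmax + beam.range_layer_spacing_mm * 0.999,
                               beam.range_layer_spacing_mm)
            for R in layers:
                bidx.append(b)
                lat_u.append(ci * dl)
                lat_v.append(cj * dl)
                rng_mm.append(float(R))
    return SpotGrid(
        list(beams),
        np.asarray(bidx, dtype=np.int32),
        np.asarray(lat_u, dtype=np.float64),
        np.asarray(lat_v, dtype=np.float64),
        np.asarray(rng_mm, dtype=np.float64),
    )


# --------------------------------------------------------------------------
# influence matrices


@dataclass
class InfluenceMatrix:
    """Sparse spot->voxel dose per unit weight per fraction (Gy-RBE)."""

    matrix: sparse.csr_matrix  # (n_spots, n_voxels)
    grid: Grid
    scenario: Scenario

    def __post_init__(self) -> None:
        self._matrix_T = None

    @property
    def n_spots(self) -> int:
        return self.matrix.shape[0]

    @property
    def matrix_T(self) -> sparse.csr_matrix:
        """Cached CSR transpose (voxels x spots) for fast dose evaluation."""
        if self._matrix_T is None:
            self._matrix_T = self.matrix.T.tocsr()
        return self._matrix_T

    def dose(self, weights: np.ndarray, n_fractions: int = 1) -> np.ndarray:
        return compute_dose(self, weights, n_fractions)


def compute_dose(
    influence: InfluenceMatrix, weights: np.ndarray, n_fractions: int = 1
) -> np.ndarray:
    """Course dose grid: weights^T x influence x n_fractions (Gy-RBE)."""
    w = np.asarray(weights, dtype=np.float64)
    if w.ndim != 1 or len(w) != influence.n_spots:
        raise ValueError(f"expected {influence.n_spots} weights, got shape {w.shape}")
    if np.any(w < 0):
        raise ValueError("spot weights must be non-negative")
    flat = influence.matrix_T.dot(w) * float(n_fractions)
    return flat.reshape(influence.grid.shape)


def build_influence(
    phantom: Phantom,
    spots: SpotGrid,
    scenario: Scenario = NOMINAL,
    relative_floor: float = 2e-3,
    lateral_cutoff_sigmas: float = 3.0,
    geometries: dict[int, BeamGeometry] | None = None,
) -> InfluenceMatrix:
    """Assemble the sparse influence matrix for one scenario.

    The scenario's setup shift rigidly displaces the patient relative to
    the beams (dose is evaluated at ``x + shift``), and the range scale
    multiplies every WED.  Entries below ``relative_floor`` of a spot's
    maximum, or laterally beyond ``lateral_cutoff_sigmas``, are dropped,
    and dose is scored in tissue only: air voxels (density below 5% of
    water), where a proton deposits next to nothing, carry no entries.
    """
    grid = phantom.grid
    n_vox = grid.n_voxels
    shift = np.asarray(scenario.setup_shift_mm)

    tissue = np.nonzero(phantom.density.ravel() >= 0.05)[0]
    idx = np.stack(np.unravel_index(tissue, grid.shape), axis=1)
    pts = idx * np.asarray(grid.spacing_mm) + np.asarray(grid.origin_mm) + shift

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for b, beam in enumerate(spots.beams):
        sel = np.nonzero(spots.beam_index == b)[0]
        if len(sel) == 0:
            continue
        geom = (
            geometries[b]
            if geometries is not None and b in geometries
            else BeamGeometry(phantom, beam)
        )
        pu, pv, _ = geom.beam_coords(pts)
        wed = geom.wed_at(pts) * scenario.range_scale
        sigma = beam.lateral_sigma_mm
        cut = lateral_cutoff_sigmas * sigma
        # bin voxels laterally for fast windowed lookup per spot
        cell = cut
        ku = np.floor(pu / cell).astype(np.int64)
        kv = np.floor(pv / cell).astype(np.int64)
        order = np.lexsort((kv, ku))
        ku_s, kv_s = ku[order], kv[order]
        keys = ku_s * (2**20) + kv_s
        uniq, starts = np.unique(keys, return_index=True)
        cell_index = {int(k): (int(s), int(e)) for k, s, e in
                      zip(uniq, starts, np.append(starts[1:], len(keys)))}

        for si in sel:
            a, c, R = spots.lat_u[si], spots.lat_v[si], spots.range_mm[si]
            ka, kc = int(np.floor(a / cell)), int(np.floor(c / cell))
            cand_parts = []
            for du in (-1, 0, 1):
                for dv in (-1, 0, 1):
                    key = (ka + du) * (2**20) + (kc + dv)
                    se = cell_index.get(key)
                    if se is not None:
                        cand_parts.append(order[se[0]:se[1]])
            if not cand_parts:
                continue
            cand = np.concatenate(cand_parts)
            r2 = (pu[cand] - a) ** 2 + (pv[cand] - c) ** 2
            near = cand[r2 <= cut * cut]
            if len(near) == 0:
                continue
            g = np.exp(-((pu[near] - a) ** 2 + (pv[near] - c) ** 2) / (2 * sigma**2))
            depth = bragg_curve(wed[near], R)
            dose = g * depth
            keep = dose >= relative_floor * dose.max()
            near, dose = near[keep], dose[keep]
            if len(near) == 0:
                continue
            rows.append(np.full(len(near), si, dtype=np.int64))
            cols.append(tissue[near])
            vals.append(dose)

    if rows:
        mat = sparse.coo_matrix(
            (
                np.concatenate(vals).astype(np.float64),
                (np.concatenate(rows), np.concatenate(cols)),
            ),
            shape=(spots.n_spots, n_vox),
        ).tocsr()
    else:
        mat = sparse.csr_matrix((spots.n_spots, n_vox), dtype=np.float64)
    return InfluenceMatrix(mat, grid, scenario)


def build_scenario_influences(
    phantom: Phantom,
    spots: SpotGrid,
    scenarios: Sequence[Scenario],
    relative_floor: float = 2e-3,
) -> list[InfluenceMatrix]:
    """Influence matrices for all scenarios, sharing per-beam geometry."""
    geoms = {b: BeamGeometry(phantom, beam) for b, beam in enumerate(spots.beams)}
    return [
        build_influence(phantom, spots, sc, relative_floor=relative_floor, geometries=geoms)
        for sc in scenarios
    ]
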