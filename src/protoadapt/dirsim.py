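"""Simulated deformable-registration contour propagation.

Real adaptive workflows propagate the planning contours onto the daily
image with several DIR algorithms; the propagated sets differ from each
other and from the physician-drawn ("clinical") contours.  This module
emulates that behaviour without any registration: each simulated
algorithm warps the daily ground-truth contours by the sum of

* a per-algorithm *systematic bias* field, fixed across fractions for a
  given algorithm (intensity-based DIRs have characteristic, correlated
  failure modes), and
* an independent *random* field, redrawn per fraction.

Both fields are Gaussian-smoothed white noise.  Contour quality is
controlled by a Dice acceptance band: out-of-band draws are re-sampled
with a perturbed seed a bounded number of times before erroring, which
guarantees "reasonable" contours while still allowing the ensembles to
occasionally miss ground-truth voxels entirely — the failure mode that
motivates uncertainty-aware adaptation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import smooth_random_field, warp_mask
from .phantoms import Phantom
from .structures import Structure, StructureSet, dice


@dataclass(frozen=True)
class DirNoiseModel:
    """Noise model for simulated DIR contour propagation.

    bias_amp_mm / random_amp_mm may be scalars (shared by all
    algorithms) or per-algorithm sequences of length ``n_algorithms``.
    ``target_dice_band`` is the (low, high) acceptance band for the Dice
    overlap between each simulated structure and the clinical one.
    """

    n_algorithms: int = 3
    bias_amp_mm: float | tuple[float, ...] = 1.5
    random_amp_mm: float | tuple[float, ...] = 1.0
    correlation_length_mm: float = 25.0
    target_dice_band: tuple[float, float] = (0.70, 1.0)
    seed: int = 0
    max_retries: int = 10

    def __post_init__(self) -> None:
        if self.n_algorithms < 2:
            raise ValueError("need at least two simulated DIR algorithms")
        lo, hi = self.target_dice_band
        if not (0.0 < lo < hi <= 1.0):
            raise ValueError(f"invalid dice band {self.target_dice_band}")
        for amp in (*self._per_algorithm(self.bias_amp_mm), *self._per_algorithm(self.random_amp_mm)):
            if amp < 0:
                raise ValueError("noise amplitudes must be >= 0")
        if self.correlation_length_mm <= 0:
            raise ValueError("correlation_length_mm must be > 0")

    def _per_algorithm(self, amp) -> tuple[float, ...]:
        if np.isscalar(amp):
            return tuple(float(amp) for _ in range(self.n_algorithms))
        amp = tuple(float(a) for a in amp)
        if len(amp) != self.n_algorithms:
            raise ValueError("per-algorithm amplitude length mismatch")
        return amp

    @property
    def bias_amps(self) -> tuple[float, ...]:
        return self._per_algorithm(self.bias_amp_mm)

    @property
    def random_amps(self) -> tuple[float, ...]:
        return self._per_algorithm(self.random_amp_mm)


class DiceBandError(RuntimeError):
    pass


def simulate_dir_sets(daily: Phantom, noise: DirNoiseModel) -> list[StructureSet]:
    """Simulate DIR-propagated structure sets on a daily phantom.

    Returns ``noise.n_algorithms`` structure sets on the daily grid, each
    the clinical set warped by that algorithm's bias + random field.
    Every structure's Dice against its clinical mask is guaranteed to lie
    in ``target_dice_band`` (after bounded re-sampling), or a
    :class:`DiceBandError` naming the offending structure is raised.

    With all amplitudes zero, each simulated set equals the clinical set.
    """
    clinical = daily.clinical_structures
    grid = daily.grid
    lo, hi = noise.target_dice_band
    seed0 = int(noise.seed) % (2**31)
    out: list[StructureSet] = []
    for a, (bias_amp, rand_amp) in enumerate(zip(noise.bias_amps, noise.random_amps)):
        accepted = None
        worst: tuple[str, float] | None = None
        for attempt in range(noise.max_retries + 1):
            # bias is systematic per algorithm: no fraction index in its
            # seed.  If the band is still unreachable halfway through the
            # retry budget the bias itself is redrawn — the analogue of a
            # plausibility check rejecting one algorithm's propagation.
            bias_seed = (
                [seed0, a, 0]
                if attempt <= noise.max_retries // 3
                else [seed0, a, 0, daily.fraction_index, attempt]
            )
            bias = smooth_random_field(
                grid, bias_amp, noise.correlation_length_mm, bias_seed
            )
            rand = smooth_random_field(
                grid,
                rand_amp,
                noise.correlation_length_mm,
                [seed0, a, 1, daily.fraction_index, attempt],
            )
            field = bias + rand
            structures = {
                name: Structure(warp_mask(s.mask, field), s.role)
                for name, s in clinical.structures.items()
            }
            ok = True
            for name, s in structures.items():
                d = dice(s.mask, clinical[name].mask)
                if not (lo <= d <= hi):
                    ok = False
                    if worst is None or d < worst[1]:
                        worst = (name, d)
                    break
            if ok:
                accepted = StructureSet(grid, structures, clinical.priority_mode)
                break
        if accepted is None:
            name, d = worst if worst is not None else ("?", float("nan"))
            raise DiceBandError(
                f"algorithm {a}: structure {name!r} Dice {d:.3f} outside band "
                f"[{lo}, {hi}] after {noise.max_retries} retries"
            )
        out.append(accepted)
    return out


def missed_clinical_voxels(
    clinical: StructureSet, dir_sets: list[StructureSet], name: str
) -> np.ndarray:
    """Clinical voxels of ``name`` not covered by any simulated set."""
    covered = np.zeros(clinical.grid.shape, dtype=bool)
    for s in dir_sets:
        covered |= s[name].mask
    return clinical[name].mask & ~covered
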