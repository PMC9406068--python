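import numpy as np
import pytest

from protoadapt.grids import Grid
from protoadapt.phantoms import PhantomSpec, generate_phantom
from protoadapt.structures import Structure, StructureSet


@pytest.fixture(scope="session")
def abdomen_phantom():
    return generate_phantom(PhantomSpec(template="abdomen"))


@pytest.fixture(scope="session")
def hn_phantom():
    return generate_phantom(PhantomSpec(template="head_neck"))


@pytest.fixture
def small_grid():
    return Grid((16, 16, 16), (2.0, 2.0, 2.0))


def random_mask(rng, shape, p=0.3):
    return rng.random(shape) < p


def sphere_mask(grid: Grid, center_mm, radius_mm):
    X, Y, Z = grid.voxel_centers_mm()
    return (X - center_mm[0]) ** 2 + (Y - center_mm[1]) ** 2 + (Z - center_mm[2]) ** 2 <= radius_mm**2


def simple_structure_set(grid: Grid, masks: dict):
    """masks: name -> (mask, role)"""
    return StructureSet(grid, {n: Structure(m, r) for n, (m, r) in masks.items()})
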