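"""NIfTI / JSON artifact I/O.

Phantoms are written as one float32 density volume plus one uint8 mask
per structure; the affine encodes spacing and origin.  A JSON manifest
records the roster, roles, seeds and fraction indices so a cohort can
be reloaded without re-generation.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import Grid
from .phantoms import Phantom
from .structures import Structure, StructureSet


def write_nifti(path: Path, data: np.ndarray, grid: Grid) -> None:
    img = nib.Nifti1Image(np.asarray(data), grid.affine())
    nib.save(img, str(path))


def read_nifti(path: Path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    aff = img.affine
    grid = Grid(tuple(data.shape), tuple(np.diag(aff)[:3].tolist()), tuple(aff[:3, 3].tolist()))
    return data, grid


def write_phantom(directory: Path, phantom: Phantom, prefix: str = "phantom") -> dict:
    """Write density + one mask file per structure; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_nifti(directory / f"{prefix}_density.nii", phantom.density.astype(np.float32), phantom.grid)
    roster = {}
    for name, s in phantom.clinical_structures.structures.items():
        fname = f"{prefix}_mask_{name}.nii"
        write_nifti(directory / fname, s.mask.astype(np.uint8), phantom.grid)
        roster[name] = {"role": s.role, "file": fname}
    manifest = {
        "prefix": prefix,
        "template": phantom.template,
        "fraction_index": phantom.fraction_index,
        "grid": {
            "shape": list(phantom.grid.shape),
            "spacing_mm": list(phantom.grid.spacing_mm),
            "origin_mm": list(phantom.grid.origin_mm),
        },
        "priority_mode": phantom.clinical_structures.priority_mode,
        "structures": roster,
        "density_file": f"{prefix}_density.nii",
    }
    with open(directory / f"{prefix}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_phantom(directory: Path, prefix: str = "phantom") -> Phantom:
    directory = Path(directory)
    with open(directory / f"{prefix}_manifest.json") as fh:
        manifest = json.load(fh)
    density, grid = read_nifti(directory / manifest["density_file"])
    structures = {}
    for name, entry in manifest["structures"].items():
        mask, _ = read_nifti(directory / entry["file"])
        structures[name] = Structure(mask.astype(bool), entry["role"])
    sset = StructureSet(grid, structures, manifest["priority_mode"])
    return Phantom(
        grid,
        density.astype(np.float32),
        sset,
        manifest["template"],
        fraction_index=int(manifest["fraction_index"]),
    )
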