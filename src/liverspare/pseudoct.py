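"""Bulk-density pseudo-CT for dose calculation on MR-only geometry.

Dose calculation needs electron density, which MR does not measure, so each
body voxel is assigned one of three population relative-electron-density
(rED) values: lung 0.328, vertebrae 1.153, remaining tissue 0.988.  Voxels
outside the body carry 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import StructureSet, VoxelImage


@dataclass
class DensityConfig:
    lung_red: float = 0.328
    vertebrae_red: float = 1.153
    tissue_red: float = 0.988
    outside_body_red: float = 0.0
    #: first matching structure wins for voxels in several masks
    override_priority: tuple[str, ...] = ("vertebrae", "lung", "tissue")

    def __post_init__(self) -> None:
        for v in (self.lung_red, self.vertebrae_red, self.tissue_red, self.outside_body_red):
            if v < 0:
                raise ValueError("rED values must be >= 0")

    def value_for(self, name: str) -> float:
        return {"lung": self.lung_red, "vertebrae": self.vertebrae_red, "tissue": self.tissue_red}[name]


def apply_density_overrides(
    structures: StructureSet, config: DensityConfig | None = None
) -> VoxelImage:
    """Assign one rED value to every body voxel by override priority.

    'tissue' means any body voxel not claimed by a higher-priority structure.
    Structures absent from the set simply claim nothing.
    """
    config = config or DensityConfig()
    if "body" not in structures:
        raise ValueError("structure set must contain a 'body' mask")
    body = structures["body"]
    red = np.full(body.shape, config.outside_body_red, dtype=float)
    assigned = np.zeros(body.shape, dtype=bool)
    for name in config.override_priority:
        if name == "tissue":
            sel = body & ~assigned
        elif name in structures:
            sel = structures[name] & body & ~assigned
        else:
            continue
        red[sel] = config.value_for(name)
        assigned |= sel
    # any body voxel left unassigned (tissue missing from priority) -> tissue
    leftover = body & ~assigned
    red[leftover] = config.tissue_red
    return VoxelImage(red, structures.spacing, structures.origin)
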