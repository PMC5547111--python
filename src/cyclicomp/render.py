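"""Raster rendering of lattice states and density fields.

Species colors follow a fixed convention: three-species
games use red / blue / yellow, five-species games red / blue / green /
yellow / pink; empty sites are white.  Continuous density fields are
colored by the locally dominant species (argmax) with intensity equal to
its local density, and drawn white where the total density is below a
floor.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
from PIL import Image

from .lattice import LatticeState
from .pde import DensityField

__all__ = ["species_palette", "render_snapshot"]

_PALETTE3 = [(220, 30, 30), (40, 60, 220), (235, 200, 30)]
_PALETTE5 = [
    (220, 30, 30),
    (40, 60, 220),
    (40, 170, 60),
    (235, 200, 30),
    (235, 120, 200),
]
_WHITE = (255, 255, 255)


def species_palette(n_species: int) -> list:
    """RGB colors for ``n_species`` species."""
    if n_species <= 3:
        return _PALETTE3[:n_species]
    if n_species <= 5:
        return _PALETTE5[:n_species]
    raise ValueError("palette defined for up to five species")


def _lattice_rgb(state: LatticeState, n_species: int) -> np.ndarray:
    pal = np.array(species_palette(n_species) + [_WHITE], dtype=np.uint8)
    idx = state.grid.astype(np.int32)
    idx[idx < 0] = n_species  # empty -> white
    return pal[idx]


def _field_rgb(fld: DensityField, floor: float = 1e-3) -> np.ndarray:
    n = fld.grids.shape[0]
    pal = np.array(species_palette(n), dtype=float)
    dominant = fld.grids.argmax(axis=0)
    intensity = np.clip(fld.grids.max(axis=0), 0.0, 1.0)[..., None]
    rgb = pal[dominant] * intensity + 255.0 * (1.0 - intensity)
    rgb[fld.total_density < floor] = 255.0
    return rgb.astype(np.uint8)


def render_snapshot(
    state: Union[LatticeState, DensityField],
    path,
    n_species: int = 0,
    scale: int = 1,
) -> Path:
    """Write a PNG (or PPM) snapshot, one pixel block per site.

    For a :class:`LatticeState`, ``n_species`` must be given (the grid
    alone does not know how many species the model has).  Output bytes
    are deterministic for a fixed input.
    """
    if isinstance(state, LatticeState):
        if n_species <= 0:
            raise ValueError("n_species required for lattice snapshots")
        rgb = _lattice_rgb(state, n_species)
    else:
        rgb = _field_rgb(state)
    if scale > 1:
        rgb = np.kron(rgb, np.ones((scale, scale, 1), dtype=np.uint8))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(rgb).save(path)
    return path
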