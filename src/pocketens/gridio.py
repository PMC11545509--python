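"""OpenDX scalar-grid IO for occupancy maps (trajectory-pocket-tool layout)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from gridData import Grid

from .pockets import OccupancyGrid

__all__ = ["write_dx", "read_dx"]


def write_dx(grid: OccupancyGrid, path: str | Path) -> None:
    """Write the occupancy grid as an OpenDX scalar field.

    Sample points are voxel centers, so the DX origin is offset half a
    voxel from the grid's box corner.
    """
    g = Grid(
        grid.occupancy,
        origin=np.asarray(grid.origin) + 0.5 * grid.spacing,
        delta=[grid.spacing] * 3,
    )
    g.export(str(path), file_format="dx")


def read_dx(path: str | Path) -> OccupancyGrid:
    """Read an OpenDX scalar field back into an :class:`OccupancyGrid`.

    Frequencies are stored directly (``n_snapshots`` is 1 so occupancy
    equals the stored values)."""
    g = Grid(str(path))
    spacing = float(g.delta[0])
    if not np.allclose(g.delta, spacing):
        raise ValueError("anisotropic grids are not supported")
    return OccupancyGrid(
        origin=np.asarray(g.origin) - 0.5 * spacing,
        spacing=spacing,
        dims=tuple(g.grid.shape),
        counts=np.asarray(g.grid, dtype=float),
        n_snapshots=1,
    )
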