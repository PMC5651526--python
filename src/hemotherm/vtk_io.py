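"""Minimal legacy-ASCII VTK output for the structured surrogate grids."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import Grid

__all__ = ["write_structured_grid"]


def write_structured_grid(path: str | Path, grid: Grid,
                          cell_data: dict[str, np.ndarray] | None = None
                          ) -> None:
    """Write the grid (and optional per-cell fields) as legacy ASCII VTK.

    Points are the face corners in the (x, transverse) plane; cell data
    arrays must have shape (nx, ny).  NaNs (inactive cells) are written
    as -1e30 so viewers can threshold them away.
    """
    path = Path(path)
    nx, ny = grid.nx, grid.ny
    lines = [
        "# vtk DataFile Version 3.0",
        "hemotherm surrogate grid",
        "ASCII",
        "DATASET STRUCTURED_GRID",
        f"DIMENSIONS {nx + 1} {ny + 1} 1",
        f"POINTS {(nx + 1) * (ny + 1)} float",
    ]
    for y in grid.yf:
        for x in grid.xf:
            lines.append(f"{x:.8e} {y:.8e} 0.0")
    lines.append(f"CELL_DATA {nx * ny}")
    data = {"zone": grid.zone.astype(float)}
    if cell_data:
        data.update(cell_data)
    for name, arr in data.items():
        arr = np.asarray(arr, dtype=float)
        arr = np.where(np.isfinite(arr), arr, -1e30)
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        # VTK orders cells x-fastest
        lines.extend(f"{v:.8e}" for v in arr.ravel(order="F"))
    path.write_text("\n".join(lines) + "\n")
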