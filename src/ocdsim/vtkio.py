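"""Minimal legacy-ASCII VTK output of lattice cell fields.

Writes the defect lattice as a VTK structured grid (an (r, z) slice of
the axisymmetric model) with one CELL_DATA scalar array per field map.
The writer covers only what this package needs; it emits plain-text
version 2.0 legacy files readable by ParaView and VTK.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .config import RunConfig

__all__ = ["write_lattice_vtk"]


def write_lattice_vtk(path: str | Path, config: RunConfig,
                      fields: dict[str, np.ndarray]) -> None:
    h = config.element_size
    first = next(iter(fields.values()))
    n_rows, n_cols = first.shape
    nx, ny = n_cols + 1, n_rows + 1
    lines = [
        "# vtk DataFile Version 2.0",
        "osteochondral defect lattice fields",
        "ASCII",
        "DATASET STRUCTURED_GRID",
        f"DIMENSIONS {nx} {ny} 1",
        f"POINTS {nx * ny} float",
    ]
    for j in range(ny):
        for i in range(nx):
            lines.append(f"{i * h:.6g} {j * h:.6g} 0")
    lines.append(f"CELL_DATA {n_rows * n_cols}")
    for name, grid in fields.items():
        if grid.shape != (n_rows, n_cols):
            raise ValueError(f"field {name!r} has mismatched shape")
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.6g}" for v in np.asarray(grid, float).ravel())
    Path(path).write_text("\n".join(lines) + "\n")
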