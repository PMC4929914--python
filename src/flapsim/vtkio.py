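"""Legacy-VTK ASCII export of structured-grid fields.

Writes RECTILINEAR_GRID files with cell-centered scalars/vectors attached
as point data on the cell-center lattice, readable by ParaView/VisIt.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .solver.grid import StructuredGrid

__all__ = ["write_rectilinear_vtk"]


def write_rectilinear_vtk(
    path: str | Path,
    grid: StructuredGrid,
    scalars: dict[str, np.ndarray] | None = None,
    vectors: dict[str, np.ndarray] | None = None,
    title: str = "flapsim field snapshot",
) -> None:
    """Write cell-centered fields on the cell-center lattice.

    Scalars have shape (nx, ny, nz); vectors (nx, ny, nz, 3).
    """
    scalars = scalars or {}
    vectors = vectors or {}
    nx, ny, nz = grid.shape
    npts = nx * ny * nz
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"X_COORDINATES {nx} double",
        " ".join(f"{x:.9g}" for x in grid.xc),
        f"Y_COORDINATES {ny} double",
        " ".join(f"{y:.9g}" for y in grid.yc),
        f"Z_COORDINATES {nz} double",
        " ".join(f"{z:.9g}" for z in grid.zc),
        f"POINT_DATA {npts}",
    ]
    for name, field in scalars.items():
        if field.shape != (nx, ny, nz):
            raise ValueError(f"scalar {name!r} has shape {field.shape}")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK expects x fastest
        flat = np.asarray(field, dtype=float).transpose(2, 1, 0).ravel()
        lines.extend(" ".join(f"{v:.6g}" for v in flat[i:i + 9])
                     for i in range(0, flat.size, 9))
    for name, field in vectors.items():
        if field.shape != (nx, ny, nz, 3):
            raise ValueError(f"vector {name!r} has shape {field.shape}")
        lines.append(f"VECTORS {name} double")
        flat = np.asarray(field, dtype=float).transpose(2, 1, 0, 3).reshape(-1, 3)
        lines.extend(" ".join(f"{v:.6g}" for v in row) for row in flat)
    Path(path).write_text("\n".join(lines) + "\n")
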