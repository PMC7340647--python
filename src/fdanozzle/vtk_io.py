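"""Minimal legacy-VTK (structured points) ASCII writer for field snapshots.

Writes density, velocity and optional derived scalar fields on the uniform
lattice so snapshots open directly in ParaView.  Legacy ASCII is used
deliberately: it is self-contained and needs no third-party writer.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_vtk_image(
    path: str | Path,
    dx: float,
    origin: tuple[float, float, float],
    scalars: dict[str, np.ndarray] | None = None,
    vectors: dict[str, np.ndarray] | None = None,
) -> None:
    """Write point data on a uniform grid as legacy VTK STRUCTURED_POINTS.

    Scalar arrays have shape (nx, ny, nz); vector arrays (nx, ny, nz, 3).
    VTK expects x varying fastest, so arrays are transposed on output.
    """
    scalars = scalars or {}
    vectors = vectors or {}
    sample = next(iter({**scalars, **vectors}.values()))
    nx, ny, nz = sample.shape[:3]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfdanozzle field snapshot\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]} {origin[1]} {origin[2]}\n")
        fh.write(f"SPACING {dx} {dx} {dx}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in scalars.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            flat = np.asarray(arr, dtype=float).transpose(2, 1, 0).ravel()
            np.savetxt(fh, flat, fmt="%.9g")
        for name, arr in vectors.items():
            fh.write(f"VECTORS {name} double\n")
            flat = np.asarray(arr, dtype=float).transpose(2, 1, 0, 3).reshape(-1, 3)
            np.savetxt(fh, flat, fmt="%.9g")


def read_vtk_dimensions(path: str | Path) -> tuple[int, int, int]:
    """Header-only sanity reader (round-trip checks)."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("DIMENSIONS"):
                _, a, b, c = line.split()
                return int(a), int(b), int(c)
    raise ValueError(f"{path}: no DIMENSIONS line")
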