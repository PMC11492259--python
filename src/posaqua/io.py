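"""Plain-text file formats: (extended) XYZ, Gaussian-cube, YAML configs.

Extended-XYZ here means the standard XYZ layout with a ``key=value``
comment line and an optional per-atom charge column::

    9
    box=15.64 energy=-4200.1 density=0.998
    O  1.234 5.678 9.012 -0.8476
    ...
"""

from __future__ import annotations

import numpy as np

from .constants import ANGSTROM_PER_BOHR

__all__ = ["write_xyz_frame", "read_xyz_frames", "write_cube"]


def write_xyz_frame(fh, symbols, coords, comment_fields=None, charges=None):
    coords = np.asarray(coords)
    fh.write(f"{len(symbols)}\n")
    fields = comment_fields or {}
    fh.write(" ".join(f"{k}={v}" for k, v in fields.items()) + "\n")
    for i, (s, xyz) in enumerate(zip(symbols, coords)):
        line = f"{s:2s} {xyz[0]:15.8f} {xyz[1]:15.8f} {xyz[2]:15.8f}"
        if charges is not None:
            line += f" {charges[i]:12.6f}"
        fh.write(line + "\n")


def _parse_comment(line: str) -> dict:
    out = {}
    for tok in line.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            try:
                out[k] = float(v)
            except ValueError:
                out[k] = v
    return out


def read_xyz_frames(fh):
    """Yield (symbols, coords, fields, charges-or-None) per frame."""
    while True:
        header = fh.readline()
        if not header.strip():
            return
        n = int(header)
        fields = _parse_comment(fh.readline())
        symbols, rows, charges = [], [], []
        for _ in range(n):
            parts = fh.readline().split()
            symbols.append(parts[0])
            rows.append([float(x) for x in parts[1:4]])
            if len(parts) > 4:
                charges.append(float(parts[4]))
        yield (symbols, np.array(rows), fields,
               np.array(charges) if charges else None)


def write_cube(fh, atoms, origin_bohr, axes_bohr, data, comment="posaqua field"):
    """Write a Gaussian-cube scalar field.

    atoms: list of (Z, x, y, z) with positions in bohr;
    axes_bohr: (3, 3) voxel step vectors; data: (nx, ny, nz) array.
    """
    data = np.asarray(data)
    nx, ny, nz = data.shape
    fh.write(comment + "\n")
    fh.write("scalar field written by posaqua\n")
    fh.write(f"{len(atoms):5d} {origin_bohr[0]:12.6f} "
             f"{origin_bohr[1]:12.6f} {origin_bohr[2]:12.6f}\n")
    for n, ax in zip((nx, ny, nz), axes_bohr):
        fh.write(f"{n:5d} {ax[0]:12.6f} {ax[1]:12.6f} {ax[2]:12.6f}\n")
    for z, x, y, zz in atoms:
        fh.write(f"{int(z):5d} {float(z):12.6f} {x:12.6f} {y:12.6f} {zz:12.6f}\n")
    flat = data.reshape(nx * ny, nz)
    for row in flat:
        for i in range(0, nz, 6):
            fh.write("".join(f"{v:13.5E}" for v in row[i:i + 6]) + "\n")


def bohr_to_angstrom(x):
    return np.asarray(x) * ANGSTROM_PER_BOHR
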