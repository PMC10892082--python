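"""Serialization: XYZ-style chain text, CA-only PDB records, CSV tables.

The native chain format is whitespace-delimited text, one monomer per line:
``index x y z [label]`` with coordinates in Angstrom, preceded by comment
lines starting with ``#`` (the writer records the bond length there).  The
PDB writer emits standard fixed-width ATOM records with a CA atom per
residue for interoperability with structure viewers and readers.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .conformation import CdfTable, Conformation, ContactRecord


def write_xyz(conf: Conformation, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# tangentchain chain n={conf.n} bond_length={conf.bond_length!r}\n")
        for k, row in enumerate(conf.coords):
            line = f"{k} " + " ".join(f"{c:.10f}" for c in row)
            if conf.labels is not None:
                line += f" {conf.labels[k]}"
            fh.write(line + "\n")


def read_xyz(path, bond_length: Optional[float] = None) -> Conformation:
    path = Path(path)
    coords: List[List[float]] = []
    labels: List[str] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if bond_length is None and "bond_length=" in line:
                    bond_length = float(line.split("bond_length=")[1].split()[0])
                continue
            parts = line.split()
            has_label = not _is_float(parts[-1])
            vals = parts[1 : len(parts) - (1 if has_label else 0)]
            coords.append([float(v) for v in vals])
            if has_label:
                labels.append(parts[-1])
    if labels and len(labels) != len(coords):
        raise ValueError("some lines carry labels and some do not")
    return Conformation(
        np.array(coords),
        bond_length=bond_length if bond_length is not None else 3.81,
        labels=np.array(labels, dtype=object) if labels else None,
    )


def _is_float(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_ca_pdb(conf: Conformation, path, chain_id: str = "A") -> None:
    """CA-only PDB records (GLY residues); coordinates truncated to 3 decimals."""
    if conf.dim != 3:
        raise ValueError("PDB output requires 3D coordinates")
    path = Path(path)
    with path.open("w") as fh:
        for k, (x, y, z) in enumerate(conf.coords, start=1):
            fh.write(
                f"ATOM  {k:5d}  CA  GLY {chain_id}{k:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("TER\nEND\n")


def write_contacts_csv(records: Sequence[ContactRecord], path) -> None:
    """Columns: i, j, separation, distance_A, near_flag."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["i", "j", "separation", "distance_A", "near_flag"])
        for r in records:
            w.writerow([r.i, r.j, r.separation, f"{r.distance:.6f}", int(r.near_flag)])


def write_cdf_csv(cdf: CdfTable, path, max_rows: Optional[int] = None) -> None:
    """Columns: x_inverse_A, cumulative_p.  Optionally thinned to max_rows."""
    x, p = cdf.x, cdf.p
    if max_rows is not None and x.size > max_rows:
        idx = np.linspace(0, x.size - 1, max_rows).astype(int)
        x, p = x[idx], p[idx]
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_inverse_A", "cumulative_p"])
        for xi, pi in zip(x, p):
            w.writerow([f"{xi:.8g}", f"{pi:.8g}"])
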