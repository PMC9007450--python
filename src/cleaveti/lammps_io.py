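"""Read/write LAMMPS-style molecular data files (``full`` atom style) and XYZ.

Supported sections: Masses, Atoms (full: id mol type q x y z), Bonds,
Angles, Dihedrals.  Coefficient sections (Bond Coeffs, Angle Coeffs,
Dihedral Coeffs) are parsed into a partial force field when present.
Unknown sections raise an error naming the offending line.
"""

from __future__ import annotations

import numpy as np

from .crystal import Crystal
from .forcefield import ForceField

_KNOWN_SECTIONS = {
    "Masses", "Atoms", "Bonds", "Angles", "Dihedrals", "Velocities",
    "Bond Coeffs", "Angle Coeffs", "Dihedral Coeffs", "Pair Coeffs",
}

_HEADER_KEYS = {
    "atoms", "bonds", "angles", "dihedrals", "impropers",
    "atom types", "bond types", "angle types", "dihedral types",
    "improper types",
}


class DataFileError(ValueError):
    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


def _strip(line: str) -> str:
    return line.split("#", 1)[0].strip()


def read_lammps_data(path) -> tuple[Crystal, ForceField]:
    """Parse a ``full``-style data file into a crystal plus partial force field.

    The force field carries masses-derived information implicitly via the
    crystal and any coefficient sections found; LJ/Wolf settings must still
    be supplied by configuration.
    """
    with open(path) as fh:
        lines = fh.readlines()

    counts: dict[str, int] = {}
    box = np.zeros(3)
    lo = np.zeros(3)
    idx = 1  # skip title line
    n_lines = len(lines)

    # ---- header
    while idx < n_lines:
        raw = _strip(lines[idx])
        if not raw:
            idx += 1
            continue
        parts = raw.split()
        matched = False
        for nwords in (2, 1):
            key = " ".join(parts[1:1 + nwords]) if len(parts) > nwords else ""
            if key in _HEADER_KEYS:
                counts[key] = int(parts[0])
                matched = True
                break
        if not matched:
            if raw.endswith(("xlo xhi", "ylo yhi", "zlo zhi")):
                ax = "xyz".index(raw.split()[-2][0])
                lo[ax] = float(parts[0])
                box[ax] = float(parts[1]) - float(parts[0])
                matched = True
        if not matched:
            break  # first body section title
        idx += 1

    n_atoms = counts.get("atoms", 0)
    if n_atoms == 0:
        raise DataFileError("no atoms declared in header")

    masses_by_type: dict[int, float] = {}
    atoms: dict[int, tuple] = {}
    bonds, angles, dihedrals = [], [], []
    bond_coeffs, angle_coeffs, dihedral_coeffs = {}, {}, {}

    def parse_section(name: str, start: int) -> int:
        k = start
        while k < n_lines and not _strip(lines[k]):
            k += 1
        expected = {
            "Atoms": n_atoms,
            "Masses": counts.get("atom types", 0),
            "Bonds": counts.get("bonds", 0),
            "Angles": counts.get("angles", 0),
            "Dihedrals": counts.get("dihedrals", 0),
            "Velocities": n_atoms,
            "Bond Coeffs": counts.get("bond types", 0),
            "Angle Coeffs": counts.get("angle types", 0),
            "Dihedral Coeffs": counts.get("dihedral types", 0),
            "Pair Coeffs": counts.get("atom types", 0),
        }[name]
        for _ in range(expected):
            if k >= n_lines or not _strip(lines[k]):
                raise DataFileError(f"truncated {name} section", k + 1)
            fields = _strip(lines[k]).split()
            ln = k + 1
            if name == "Masses":
                masses_by_type[int(fields[0])] = float(fields[1])
            elif name == "Atoms":
                if len(fields) < 7:
                    raise DataFileError(
                        "Atoms line is not in 'full' style "
                        "(need: id mol type q x y z)", ln)
                aid = int(fields[0])
                atoms[aid] = (int(fields[1]), int(fields[2]), float(fields[3]),
                              float(fields[4]), float(fields[5]), float(fields[6]))
            elif name in ("Bonds", "Angles", "Dihedrals"):
                sink = {"Bonds": bonds, "Angles": angles, "Dihedrals": dihedrals}[name]
                ids = [int(v) for v in fields[2:]]
                for aid in ids:
                    if aid not in atoms:
                        raise DataFileError(
                            f"{name[:-1].lower()} references missing atom id {aid}", ln)
                sink.append((int(fields[1]), *ids))
            elif name == "Bond Coeffs":
                bond_coeffs[int(fields[0]) - 1] = (float(fields[1]), float(fields[2]))
            elif name == "Angle Coeffs":
                angle_coeffs[int(fields[0]) - 1] = (float(fields[1]),
                                                    np.deg2rad(float(fields[2])))
            elif name == "Dihedral Coeffs":
                dihedral_coeffs[int(fields[0]) - 1] = (float(fields[1]),
                                                       int(fields[2]),
                                                       np.deg2rad(float(fields[3])))
            # Velocities, Pair Coeffs: skipped
            k += 1
        return k

    while idx < n_lines:
        raw = _strip(lines[idx])
        if not raw:
            idx += 1
            continue
        if raw not in _KNOWN_SECTIONS:
            raise DataFileError(f"unknown section {raw!r}", idx + 1)
        idx = parse_section(raw, idx + 1)

    if len(atoms) != n_atoms:
        raise DataFileError(f"expected {n_atoms} atoms, found {len(atoms)}")

    order = sorted(atoms)
    id_map = {aid: k for k, aid in enumerate(order)}
    mol = np.array([atoms[a][0] - 1 for a in order])
    types = np.array([atoms[a][1] - 1 for a in order])
    charges = np.array([atoms[a][2] for a in order])
    pos = np.array([[atoms[a][3], atoms[a][4], atoms[a][5]] for a in order])
    masses = np.array([masses_by_type.get(t + 1, 1.0) for t in types])

    def remap(rows, width):
        if not rows:
            return np.zeros((0, width), dtype=int)
        out = []
        for row in rows:
            out.append([row[0] - 1] + [id_map[a] for a in row[1:]])
        return np.array(out, dtype=int)

    crystal = Crystal(
        box=box,
        positions=np.mod(pos - lo, box),
        types=types,
        charges=charges,
        masses=masses,
        molecule=mol - mol.min() if len(mol) else mol,
        bonds=remap(bonds, 3),
        angles=remap(angles, 4),
        dihedrals=remap(dihedrals, 5),
    )
    ff = ForceField(bond_coeffs=bond_coeffs, angle_coeffs=angle_coeffs,
                    dihedral_coeffs=dihedral_coeffs)
    return crystal, ff


def write_lammps_data(crystal: Crystal, path, title: str = "cleaveti data file",
                      ff: ForceField | None = None) -> None:
    """Write a crystal as a ``full``-style LAMMPS data file."""
    ntypes = crystal.n_types
    masses = np.zeros(ntypes)
    for t in range(ntypes):
        sel = crystal.types == t
        masses[t] = crystal.masses[sel][0] if np.any(sel) else 1.0

    def ntypes_of(arr):
        return int(arr[:, 0].max()) + 1 if arr.size else 0

    with open(path, "w") as fh:
        fh.write(f"{title}\n\n")
        fh.write(f"{crystal.n_sites} atoms\n")
        fh.write(f"{len(crystal.bonds)} bonds\n")
        fh.write(f"{len(crystal.angles)} angles\n")
        fh.write(f"{len(crystal.dihedrals)} dihedrals\n\n")
        fh.write(f"{ntypes} atom types\n")
        fh.write(f"{ntypes_of(crystal.bonds)} bond types\n")
        fh.write(f"{ntypes_of(crystal.angles)} angle types\n")
        fh.write(f"{ntypes_of(crystal.dihedrals)} dihedral types\n\n")
        for ax, name in enumerate(("x", "y", "z")):
            fh.write(f"0.0 {crystal.box[ax]:.10f} {name}lo {name}hi\n")
        fh.write("\nMasses\n\n")
        for t in range(ntypes):
            fh.write(f"{t + 1} {masses[t]:.6f}\n")
        if ff is not None and ff.bond_coeffs:
            fh.write("\nBond Coeffs\n\n")
            for t in sorted(ff.bond_coeffs):
                k, r0 = ff.bond_coeffs[t]
                fh.write(f"{t + 1} {k:.6f} {r0:.6f}\n")
        fh.write("\nAtoms # full\n\n")
        for k in range(crystal.n_sites):
            x, y, z = crystal.positions[k]
            fh.write(f"{k + 1} {crystal.molecule[k] + 1} {crystal.types[k] + 1} "
                     f"{crystal.charges[k]: .8f} {x:.10f} {y:.10f} {z:.10f}\n")
        for name, arr in (("Bonds", crystal.bonds), ("Angles", crystal.angles),
                          ("Dihedrals", crystal.dihedrals)):
            if arr.size:
                fh.write(f"\n{name}\n\n")
                for k, row in enumerate(arr):
                    cols = " ".join(str(v + 1) for v in row[1:])
                    fh.write(f"{k + 1} {row[0] + 1} {cols}\n")


def write_xyz(crystal: Crystal, path, comment: str = "") -> None:
    """Write site coordinates as an XYZ snapshot for quick inspection."""
    labels = crystal.type_labels or tuple(f"T{t}" for t in range(crystal.n_types))
    with open(path, "a") as fh:
        fh.write(f"{crystal.n_sites}\n{comment}\n")
        for k in range(crystal.n_sites):
            lab = labels[crystal.types[k]] if crystal.types[k] < len(labels) \
                else f"T{crystal.types[k]}"
            x, y, z = crystal.positions[k]
            fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")
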