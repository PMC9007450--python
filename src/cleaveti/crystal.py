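"""Crystal structures: unit cells, supercells and toy-crystal fixtures.

Only orthorhombic cells are supported (all angles 90°), which covers the
orthorhombic molecular crystals this package targets.  A :class:`UnitCell`
is an explicit list of sites (no symmetry expansion), and a :class:`Crystal`
is a fully replicated periodic simulation box with molecular topology.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .units import AVOGADRO

# Standard atomic weights (g/mol), 2021 IUPAC abridged values.
ATOMIC_WEIGHTS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "Na": 22.990, "Mg": 24.305, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "K": 39.098, "Ca": 40.078,
}

OVERLAP_TOLERANCE = 0.1  # Å; closer sites after replication signal a malformed cell


def molar_mass_from_formula(formula: str) -> float:
    """Molar mass (g/mol) of a simple Hill-style formula like ``C6H14O6``."""
    tokens = re.findall(r"([A-Z][a-z]?)(\d*)", formula)
    mass = 0.0
    consumed = ""
    for element, count in tokens:
        if not element:
            continue
        if element not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        mass += ATOMIC_WEIGHTS[element] * (int(count) if count else 1)
        consumed += element + count
    if consumed != formula.replace(" ", ""):
        raise ValueError(f"could not parse formula {formula!r}")
    return mass


@dataclass
class UnitCell:
    """An orthorhombic unit cell given as an explicit site list.

    ``bonds``/``angles``/``dihedrals`` are integer arrays with a leading
    type column, e.g. one bond row is ``(bond_type, i, j)`` with site
    indices local to the cell.  Every site belongs to exactly one molecule.
    """

    a: float
    b: float
    c: float
    frac: np.ndarray           # (n, 3) fractional coordinates in [0, 1)
    types: np.ndarray          # (n,) integer site types, 0-based
    charges: np.ndarray        # (n,) partial charges, e
    molecule: np.ndarray       # (n,) molecule index per site, 0-based
    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=int))
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=int))
    dihedrals: np.ndarray = field(default_factory=lambda: np.zeros((0, 5), dtype=int))
    type_labels: tuple = ()

    def __post_init__(self):
        self.frac = np.atleast_2d(np.asarray(self.frac, dtype=float))
        self.types = np.asarray(self.types, dtype=int)
        self.charges = np.asarray(self.charges, dtype=float)
        self.molecule = np.asarray(self.molecule, dtype=int)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 3)
        self.angles = np.asarray(self.angles, dtype=int).reshape(-1, 4)
        self.dihedrals = np.asarray(self.dihedrals, dtype=int).reshape(-1, 5)
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("lattice lengths must be positive")
        if np.any(self.frac < 0) or np.any(self.frac >= 1):
            raise ValueError("fractional coordinates must lie in [0, 1)")
        mols = np.unique(self.molecule)
        if not np.array_equal(mols, np.arange(len(mols))):
            raise ValueError("molecule indices must be 0..Z-1")
        for arr in (self.bonds, self.angles, self.dihedrals):
            if arr.size and (arr[:, 1:].min() < 0 or arr[:, 1:].max() >= self.n_sites):
                raise ValueError("topology refers to site indices outside the cell")
        if self.bonds.size:
            same = self.molecule[self.bonds[:, 1]] == self.molecule[self.bonds[:, 2]]
            if not np.all(same):
                raise ValueError("a bond connects sites of different molecules")

    @property
    def n_sites(self) -> int:
        return len(self.frac)

    @property
    def z(self) -> int:
        """Number of molecules per cell."""
        return int(self.molecule.max()) + 1 if self.n_sites else 0

    @property
    def volume(self) -> float:
        return self.a * self.b * self.c


@dataclass
class Crystal:
    """A periodic orthorhombic simulation box with molecular topology."""

    box: np.ndarray            # (3,) box lengths
    positions: np.ndarray      # (n, 3) Cartesian, wrapped into [0, L)
    types: np.ndarray
    charges: np.ndarray
    masses: np.ndarray         # (n,) per-site masses
    molecule: np.ndarray
    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=int))
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=int))
    dihedrals: np.ndarray = field(default_factory=lambda: np.zeros((0, 5), dtype=int))
    type_labels: tuple = ()

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.types = np.asarray(self.types, dtype=int)
        self.charges = np.asarray(self.charges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.molecule = np.asarray(self.molecule, dtype=int)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 3)
        self.angles = np.asarray(self.angles, dtype=int).reshape(-1, 4)
        self.dihedrals = np.asarray(self.dihedrals, dtype=int).reshape(-1, 5)
        for arr in (self.bonds, self.angles, self.dihedrals):
            if arr.size and (arr[:, 1:].min() < 0 or arr[:, 1:].max() >= self.n_sites):
                raise ValueError("topology refers to invalid site indices")
        if self.bonds.size:
            same = self.molecule[self.bonds[:, 1]] == self.molecule[self.bonds[:, 2]]
            if not np.all(same):
                raise ValueError("a bond connects sites of different molecules")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule.max()) + 1 if self.n_sites else 0

    @property
    def n_types(self) -> int:
        return int(self.types.max()) + 1 if self.n_sites else 0

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def wrapped(self, positions: np.ndarray | None = None) -> np.ndarray:
        pos = self.positions if positions is None else positions
        return np.mod(pos, self.box)

    def copy(self) -> "Crystal":
        return replace(
            self,
            box=self.box.copy(),
            positions=self.positions.copy(),
            types=self.types.copy(),
            charges=self.charges.copy(),
            masses=self.masses.copy(),
            molecule=self.molecule.copy(),
            bonds=self.bonds.copy(),
            angles=self.angles.copy(),
            dihedrals=self.dihedrals.copy(),
        )


def build_supercell(cell: UnitCell, nx: int, ny: int, nz: int,
                    masses_by_type: np.ndarray | dict | None = None) -> Crystal:
    """Replicate a unit cell ``nx × ny × nz`` times into a periodic crystal.

    Site, molecule and topology indices are re-labelled consecutively per
    image.  Raises if any two replicated sites come closer than
    ``OVERLAP_TOLERANCE`` Å, which signals a malformed cell.
    """
    if min(nx, ny, nz) < 1:
        raise ValueError("replication counts must be >= 1")
    abc = np.array([cell.a, cell.b, cell.c])
    box = abc * np.array([nx, ny, nz], dtype=float)
    base = cell.frac * abc
    n = cell.n_sites

    positions, types, charges, molecule = [], [], [], []
    bonds, angles, dihedrals = [], [], []
    image = 0
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                shift = np.array([ix, iy, iz]) * abc
                positions.append(base + shift)
                types.append(cell.types)
                charges.append(cell.charges)
                molecule.append(cell.molecule + image * cell.z)
                off = image * n
                if cell.bonds.size:
                    bonds.append(cell.bonds + [0, off, off])
                if cell.angles.size:
                    angles.append(cell.angles + [0, off, off, off])
                if cell.dihedrals.size:
                    dihedrals.append(cell.dihedrals + [0, off, off, off, off])
                image += 1

    positions = np.mod(np.concatenate(positions), box)
    types_arr = np.concatenate(types)
    if masses_by_type is None:
        masses = np.ones(len(positions))
    elif isinstance(masses_by_type, dict):
        masses = np.array([masses_by_type[t] for t in types_arr], dtype=float)
    else:
        masses = np.asarray(masses_by_type, dtype=float)[types_arr]

    crystal = Crystal(
        box=box,
        positions=positions,
        types=types_arr,
        charges=np.concatenate(charges),
        masses=masses,
        molecule=np.concatenate(molecule),
        bonds=np.concatenate(bonds) if bonds else np.zeros((0, 3), dtype=int),
        angles=np.concatenate(angles) if angles else np.zeros((0, 4), dtype=int),
        dihedrals=np.concatenate(dihedrals) if dihedrals else np.zeros((0, 5), dtype=int),
        type_labels=cell.type_labels,
    )

    tree = cKDTree(crystal.positions, boxsize=box)
    close = tree.query_pairs(OVERLAP_TOLERANCE)
    if close:
        i, j = sorted(close)[0]
        raise ValueError(
            f"replication produced overlapping sites {i} and {j} "
            f"(distance < {OVERLAP_TOLERANCE} Å): malformed unit cell"
        )
    return crystal


def crystal_density(cell: UnitCell, molar_mass: float) -> float:
    """Crystallographic density in kg/m³ from cell volume, Z and molar mass."""
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    mass_kg = cell.z * molar_mass / AVOGADRO * 1e-3
    volume_m3 = cell.volume * 1e-30
    return mass_kg / volume_m3


def percent_error(sim_value: float, ref_value: float) -> float:
    """Signed percent deviation of ``sim_value`` from ``ref_value``.

    Returned unrounded; rounding to whole percent happens only at report time.
    """
    if ref_value == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (sim_value - ref_value) / ref_value


def make_vacuum_slab(crystal: Crystal, axis: int = 2, padding: float | None = None) -> Crystal:
    """Return a copy with vacuum added along ``axis``.

    With padding larger than the interaction cutoff the crystal no longer
    interacts with its periodic images along that axis, so a plain periodic
    energy evaluation of the padded box is a genuine slab energy.  Used as an
    independent route to the slab endpoint of the cleaving path.
    """
    slab = crystal.copy()
    pad = padding if padding is not None else crystal.box[axis]
    slab.box = slab.box.copy()
    slab.box[axis] += pad
    return slab


# ---------------------------------------------------------------------------
# Toy-crystal fixtures
# ---------------------------------------------------------------------------

# basis offset by a quarter cell so that every periodic boundary falls in an
# inter-layer gap: the default cleaving plane must never cut through a layer
_FCC_FRAC = 0.25 + np.array([
    [0.0, 0.0, 0.0],
    [0.5, 0.5, 0.0],
    [0.5, 0.0, 0.5],
    [0.0, 0.5, 0.5],
])


def fcc_cell(lattice_constant: float) -> UnitCell:
    """Four-site fcc basis cell of a monatomic (one site per molecule) solid."""
    a = lattice_constant
    return UnitCell(
        a=a, b=a, c=a,
        frac=_FCC_FRAC.copy(),
        types=np.zeros(4, dtype=int),
        charges=np.zeros(4),
        molecule=np.arange(4),
        type_labels=("LJ",),
    )


def rock_salt_cell(spacing: float, charge: float, bonded: bool = False) -> UnitCell:
    """Cubic rock-salt cell: 8 alternating ± charges, nearest-neighbour
    distance ``spacing``.

    With ``bonded=True`` the charges are paired into 4 vertical diatomic
    molecules (bond length = spacing); otherwise each ion is its own
    "molecule" (a bare ionic toy lattice).
    """
    a = 2.0 * spacing
    frac = 0.25 + np.array([
        [0.0, 0.0, 0.0],   # +
        [0.0, 0.0, 0.5],   # -
        [0.5, 0.5, 0.0],   # +
        [0.5, 0.5, 0.5],   # -
        [0.5, 0.0, 0.5],   # +
        [0.5, 0.0, 0.0],   # -
        [0.0, 0.5, 0.5],   # +
        [0.0, 0.5, 0.0],   # -
    ])
    charges = charge * np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=float)
    if bonded:
        molecule = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        bonds = np.array([[0, 0, 1], [0, 2, 3], [0, 4, 5], [0, 6, 7]])
    else:
        molecule = np.arange(8)
        bonds = np.zeros((0, 3), dtype=int)
    return UnitCell(
        a=a, b=a, c=a,
        frac=frac,
        types=np.zeros(8, dtype=int),
        charges=charges,
        molecule=molecule,
        bonds=bonds,
        type_labels=("D",),
    )


def relax_positions(crystal: Crystal, ff, ftol: float = 1e-9,
                    max_steps: int = 50000) -> Crystal:
    """Relax site positions to a local energy minimum (box fixed) with FIRE.

    FIRE (fast inertial relaxation engine) uses only forces, so it is robust
    to the energy discontinuity of the truncated LJ potential at the cutoff,
    where line-search minimisers stall.
    """
    from . import forcefield as ffmod

    table = ffmod.build_pair_table(crystal, ff)
    pos = crystal.positions.copy()
    vel = np.zeros_like(pos)
    dt, dt_max, alpha = 0.005, 0.02, 0.1
    n_pos = 0
    _, forces = ffmod.total_energy_forces(pos, crystal, ff, table)
    for _ in range(max_steps):
        if np.abs(forces).max() < ftol:
            break
        power = float(np.sum(forces * vel))
        if power > 0:
            n_pos += 1
            fnorm = np.linalg.norm(forces)
            vnorm = np.linalg.norm(vel)
            if fnorm > 0:
                vel = (1 - alpha) * vel + alpha * vnorm * forces / fnorm
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            vel[:] = 0.0
            dt *= 0.5
            alpha = 0.1
            n_pos = 0
        vel += dt * forces
        pos += dt * vel
        _, forces = ffmod.total_energy_forces(pos, crystal, ff, table)
    out = crystal.copy()
    out.positions = np.mod(pos, crystal.box)
    return out


def _minimize_lattice_constant(make_system, bracket, tol=1e-8):
    """1-D deterministic minimisation of lattice energy over a scaling length."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(make_system, bounds=bracket, method="bounded",
                          options={"xatol": tol})
    return float(res.x)


def generate_toy_crystal(kind: str, reps: tuple[int, int, int], seed: int = 0):
    """Build a deterministic, mechanically stable toy crystal plus force field.

    Supported kinds:

    ``lj_fcc``
        Monatomic Lennard-Jones fcc solid in reduced units, lattice constant
        at the energy minimum for the chosen cutoff.  Zero charges.
    ``diatomic_molecular``
        Rock-salt arrangement of rigid-ish dumbbells (±q charges joined by a
        stiff harmonic bond), real units.  Exercises bonds + electrostatics.
    ``flexible_chain``
        Crystal of 4-site zig-zag chains with bonds, angles and a dihedral,
        relaxed to a local energy minimum with L-BFGS.  Real units.

    Returns ``(crystal, forcefield)``.  The construction is fully
    deterministic; ``seed`` is recorded for provenance but no randomness is
    used.
    """
    from . import forcefield as ffmod
    from .units import REAL, REDUCED

    nx, ny, nz = reps
    if kind == "lj_fcc":
        def energy_of_a(a):
            cell = fcc_cell(a)
            crys = build_supercell(cell, nx, ny, nz)
            rc = min(2.0, 0.49 * float(crys.box.min()))
            ff = ffmod.ForceField(units=REDUCED, lj={0: (1.0, 1.0)},
                                  lj_cutoff=rc, coulomb_cutoff=rc)
            return ffmod.potential_energy(crys, ff)

        a0 = _minimize_lattice_constant(energy_of_a, (1.35, 1.75))
        cell = fcc_cell(a0)
        crystal = build_supercell(cell, nx, ny, nz)
        rc = min(2.0, 0.49 * float(crystal.box.min()))
        ff = ffmod.ForceField(units=REDUCED, lj={0: (1.0, 1.0)},
                              lj_cutoff=rc, coulomb_cutoff=rc)
        return crystal, ff

    if kind == "diatomic_molecular":
        eps, sig, q, mass = 0.65, 2.9, 0.30, 20.0

        def make_ff(box_min):
            rc = 0.49 * box_min
            return ffmod.ForceField(
                units=REAL,
                lj={0: (eps, sig)},
                lj_cutoff=rc,
                wolf_alpha=0.2,
                coulomb_cutoff=rc,
                bond_coeffs={0: (2500.0, 0.0)},  # r0 patched after minimisation
            )

        def energy_of_h(h):
            cell = rock_salt_cell(h, q, bonded=True)
            crys = build_supercell(cell, nx, ny, nz, masses_by_type={0: mass})
            ff = make_ff(float(crys.box.min()))
            ff.bond_coeffs = {0: (2500.0, h)}
            return ffmod.potential_energy(crys, ff)

        h0 = _minimize_lattice_constant(energy_of_h, (2.3, 3.6))
        cell = rock_salt_cell(h0, q, bonded=True)
        crystal = build_supercell(cell, nx, ny, nz, masses_by_type={0: mass})
        ff = make_ff(float(crystal.box.min()))
        ff.bond_coeffs = {0: (2500.0, h0)}
        # bonded-neighbour exclusion is one-sided, so the ideal lattice is not
        # exactly force-free: relax to the nearby minimum
        crystal = relax_positions(crystal, ff)
        return crystal, ff

    if kind == "flexible_chain":
        return _flexible_chain(nx, ny, nz)

    raise ValueError(f"unsupported toy crystal kind {kind!r}")


def _flexible_chain(nx, ny, nz):
    from . import forcefield as ffmod
    from .units import REAL

    bond_l, theta0 = 1.53, np.deg2rad(112.0)
    dz = bond_l * np.sin(theta0 / 2.0)
    dx = bond_l * np.cos(theta0 / 2.0)
    a_lat, gap = 4.6, 3.2
    c = 3 * dz + gap
    # zig-zag chain along z, alternating x displacement
    xyz = np.array([
        [0.0, 0.0, 0.0],
        [dx, 0.0, dz],
        [0.0, 0.0, 2 * dz],
        [dx, 0.0, 3 * dz],
    ])
    xyz -= xyz.min(axis=0)
    xyz += np.array([0.8, 2.3, gap / 2.0])
    frac = xyz / np.array([a_lat, a_lat, c])
    cell = UnitCell(
        a=a_lat, b=a_lat, c=c,
        frac=frac,
        types=np.zeros(4, dtype=int),
        charges=np.array([0.12, -0.12, -0.12, 0.12]),
        molecule=np.zeros(4, dtype=int),
        bonds=np.array([[0, 0, 1], [0, 1, 2], [0, 2, 3]]),
        angles=np.array([[0, 0, 1, 2], [0, 1, 2, 3]]),
        dihedrals=np.array([[0, 0, 1, 2, 3]]),
        type_labels=("A",),
    )
    crystal = build_supercell(cell, nx, ny, nz, masses_by_type={0: 14.0})
    rc = 0.49 * float(crystal.box.min())
    ff = ffmod.ForceField(
        units=REAL,
        lj={0: (0.45, 3.4)},
        lj_cutoff=rc,
        wolf_alpha=0.2,
        coulomb_cutoff=rc,
        bond_coeffs={0: (2000.0, bond_l)},
        angle_coeffs={0: (400.0, theta0)},
        dihedral_coeffs={0: (4.0, 1, 0.0)},
    )

    return relax_positions(crystal, ff), ff
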