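"""Internal unit systems.

``real`` units follow the conventions common in molecular force-field work:
energies in kJ/mol, lengths in Å, time in fs, masses in g/mol, charges in
elementary charges, temperature in K.  With these choices the kinetic energy
of a site is ``0.5 * m * v**2 * MV2E`` kJ/mol, with ``MV2E = 1e4`` converting
(g/mol)·(Å/fs)² to kJ/mol.

``reduced`` units are the dimensionless Lennard-Jones convention
(ε = σ = m = k_B = 1) used by the atomic toy fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

AVOGADRO = 6.02214076e23  # 1/mol


@dataclass(frozen=True)
class UnitSystem:
    """Bundle of conversion constants defining an internal unit system.

    Attributes
    ----------
    kb : Boltzmann constant, energy per K (kJ/mol/K in real units).
    mv2e : converts mass·velocity² to energy (1e4 for g/mol·(Å/fs)² -> kJ/mol).
    coulomb : Coulomb prefactor k_C, energy·length/charge².
    pressure : converts internal pressure (energy/length³) to bar.
    sfe : converts internal energy/length² to mJ/m² (166.054 for kJ/mol/Å²).
    """

    name: str
    kb: float
    mv2e: float
    coulomb: float
    pressure: float
    sfe: float


REAL = UnitSystem(
    name="real",
    kb=8.3144621e-3,          # kJ/mol/K
    mv2e=1.0e4,               # (g/mol)(Å/fs)^2 -> kJ/mol
    coulomb=138.935458,       # kJ/mol · Å / e^2
    pressure=16605.39,        # kJ/mol/Å^3 -> bar
    sfe=166.054,              # kJ/mol/Å^2 -> mJ/m^2
)

REDUCED = UnitSystem(
    name="reduced",
    kb=1.0,
    mv2e=1.0,
    coulomb=1.0,
    pressure=1.0,
    sfe=1.0,
)

_SYSTEMS = {"real": REAL, "reduced": REDUCED}


def get_units(name: str) -> UnitSystem:
    try:
        return _SYSTEMS[name]
    except KeyError:
        raise ValueError(f"unknown unit system {name!r}; expected one of {sorted(_SYSTEMS)}")
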