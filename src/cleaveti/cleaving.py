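"""The λ-coupled cleaving potential.

A cleaving plane normal to one box axis splits intermolecular interactions
into *crossing* pairs — those whose minimum-image interaction path passes
through the plane — and non-crossing pairs.  Crossing interactions are
scaled by a coupling function f(λ) with f(1) = 1 (bulk) and f(0) = 0
(slab: the system no longer interacts through the plane).  The reversible
work of switching λ from 1 to 0, per unit created area, is the surface
free energy; the derivative of the coupled potential with respect to λ
gives the thermodynamic-integration integrand, split into LJ and Coulomb
parts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import forcefield as ffmod
from .crystal import Crystal

_AXES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}


@dataclass
class CleavingSpec:
    """Where and how the crystal is cleaved.

    ``plane_position`` defaults to the periodic boundary of the normal axis
    (position 0.0), where "crossing" reduces to "the minimum-image path
    wraps the box".  ``coupling_exponent`` is the exponent n of the default
    power-law coupling f(λ) = λⁿ; high n suppresses the endpoint
    catastrophe because f'(0) = 0.
    """

    normal_axis: str | int = "z"
    plane_position: float = 0.0
    coupling_exponent: int = 4
    lam: float = 1.0
    coupling_form: str = "power"   # or "ratio": λⁿ/(λⁿ + (1−λ)ⁿ)

    def __post_init__(self):
        if self.normal_axis not in _AXES:
            raise ValueError(f"unknown axis {self.normal_axis!r}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.coupling_exponent < 2:
            raise ValueError("coupling exponent must be >= 2")

    @property
    def axis(self) -> int:
        return _AXES[self.normal_axis]

    def area(self, box: np.ndarray) -> float:
        """Area of one created surface: product of the tangent box lengths."""
        tangent = [box[k] for k in range(3) if k != self.axis]
        return float(tangent[0] * tangent[1])

    def at_lambda(self, lam: float) -> "CleavingSpec":
        return replace(self, lam=lam)


def coupling(lam: float, n: int, form: str = "power") -> tuple[float, float]:
    """Coupling function f(λ) and its derivative f'(λ).

    The default power form is f(λ) = λⁿ.  The alternative normalized-ratio
    form λⁿ/(λⁿ + (1−λ)ⁿ) shares the endpoint values and, for n ≥ 2, the
    vanishing endpoint derivatives.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    if n < 2:
        raise ValueError("coupling exponent must be >= 2")
    if form == "power":
        return lam ** n, n * lam ** (n - 1)
    if form == "ratio":
        a, b = lam ** n, (1.0 - lam) ** n
        da = n * lam ** (n - 1)
        db = -n * (1.0 - lam) ** (n - 1)
        denom = a + b
        return a / denom, (da * denom - a * (da + db)) / denom ** 2
    raise ValueError(f"unknown coupling form {form!r}")


def classify_crossing(positions: np.ndarray, box: np.ndarray,
                      i: np.ndarray, j: np.ndarray,
                      spec: CleavingSpec) -> np.ndarray:
    """Boolean mask: does the minimum-image path i→j pass through the plane?

    With s = (z_i − z_plane) mod L and Δz the minimum-image displacement,
    the pair crosses iff s + Δz falls outside [0, L].  Positions must be
    wrapped into the box.
    """
    ax = spec.axis
    length = box[ax]
    s = np.mod(positions[i, ax] - spec.plane_position, length)
    dz = positions[j, ax] - positions[i, ax]
    dz -= length * np.rint(dz / length)
    t = s + dz
    return (t < 0.0) | (t > length)


def molecules_straddling_plane(crystal: Crystal, positions: np.ndarray,
                               spec: CleavingSpec) -> np.ndarray:
    """Molecule ids whose own sites are separated by the cleaving plane.

    In a crystal cleaved between molecular layers this should never happen;
    it signals a badly placed plane or molecules escaping the lattice.
    """
    if crystal.bonds.size == 0:
        return np.array([], dtype=int)
    bi, bj = crystal.bonds[:, 1], crystal.bonds[:, 2]
    cross = classify_crossing(positions, crystal.box, bi, bj, spec)
    return np.unique(crystal.molecule[bi[cross]])


@dataclass
class CoupledEnergy:
    """Decomposed λ-coupled energy U = U_noncross + f(λ)·U_cross + U_intra."""

    u_total: float
    u_cross_lj: float
    u_cross_c: float
    u_noncross: float
    u_intra: float
    f: float
    fprime: float
    forces: np.ndarray | None = None
    virial: np.ndarray | None = None

    @property
    def u_cross(self) -> float:
        return self.u_cross_lj + self.u_cross_c


def coupled_energy(crystal: Crystal, ff: ffmod.ForceField, spec: CleavingSpec,
                   positions: np.ndarray | None = None,
                   table: ffmod.PairTable | None = None,
                   need_forces: bool = False,
                   check_straddling: bool = False) -> CoupledEnergy:
    """Evaluate the λ-coupled potential and its decomposition."""
    pos = crystal.positions if positions is None else positions
    if table is None:
        table = ffmod.build_pair_table(crystal, ff)
    f, fp = coupling(spec.lam, spec.coupling_exponent, spec.coupling_form)
    crossing = classify_crossing(pos, crystal.box, table.i, table.j, spec)
    if check_straddling:
        bad = molecules_straddling_plane(crystal, pos, spec)
        if bad.size:
            warnings.warn(
                f"molecules {bad.tolist()} straddle the cleaving plane",
                RuntimeWarning, stacklevel=2)
    rep = ffmod.evaluate(pos, crystal, ff, table, crossing=crossing,
                         f_lambda=f, need_forces=need_forces)
    return CoupledEnergy(
        u_total=rep.u_total,
        u_cross_lj=rep.u_lj_cross,
        u_cross_c=rep.u_c_cross,
        u_noncross=rep.u_noncross,
        u_intra=rep.u_intra,
        f=f, fprime=fp,
        forces=rep.forces,
        virial=rep.virial,
    )


def integrand(crystal: Crystal, ff: ffmod.ForceField, spec: CleavingSpec,
              positions: np.ndarray | None = None,
              table: ffmod.PairTable | None = None) -> tuple[float, float]:
    """TI integrand per unit area, split into (E_LJ, E_C).

    E = −f'(λ)·U_cross/(2A): positive for a stable (cohesive) crystal, so
    that ∫₀¹ E dλ ≥ 0 is the work per unit area of creating two surfaces,
    divided by their total area 2A.
    """
    ce = coupled_energy(crystal, ff, spec, positions=positions, table=table)
    area2 = 2.0 * spec.area(crystal.box)
    return (-ce.fprime * ce.u_cross_lj / area2,
            -ce.fprime * ce.u_cross_c / area2)
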