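"""Force-field evaluation: core-softened Lennard-Jones, Wolf-summation
electrostatics and intramolecular bonded terms.

The Lennard-Jones potential is replaced below a small inner radius
``r_m = r_m_fraction · σ_ij`` by a quadratic ``p0 + p1·r + p2·r²`` whose
coefficients are fixed by C² matching (value, slope, curvature) at ``r_m``.
This keeps energies finite when weakly-coupled sites approach each other
along the cleaving path, while leaving the fully coupled end states
untouched as long as no pair ever samples ``r < r_m`` there.

Electrostatics use the Wolf method: a damped, cutoff, energy-shifted pairwise
sum plus a configuration-independent self term.  A damped-shifted-force
variant (continuous forces at the cutoff) is available via
``wolf_variant="force_shifted"``.

Intramolecular nonbonded pairs separated by one or two bonds (1-2, 1-3) are
excluded; 1-4 and more distant pairs are included, optionally scaled by
``scale14``.  Intramolecular nonbonded terms always count as part of the
unscaled intramolecular energy.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

from .crystal import Crystal
from .units import REAL, UnitSystem

SQRT_PI = math.sqrt(math.pi)


@dataclass
class ForceField:
    """Parameter tables for all interaction terms.

    ``lj`` maps site type -> (ε, σ).  Pair parameters use geometric mixing
    for both ε and σ.  Bonded coefficient tables map the type column of the
    corresponding topology arrays: bonds ``(k, r0)`` (harmonic, ½k(r−r0)²),
    angles ``(k, θ0)`` with θ0 in radians, dihedrals ``(k, m, δ)`` for
    ``k·[1 + cos(mφ − δ)]``.
    """

    units: UnitSystem = REAL
    lj: dict = field(default_factory=dict)
    lj_cutoff: float = 12.0
    r_m_fraction: float = 0.5
    wolf_alpha: float = 0.075
    coulomb_cutoff: float = 14.0
    wolf_variant: str = "energy_shifted"   # or "force_shifted"
    bond_coeffs: dict = field(default_factory=dict)
    angle_coeffs: dict = field(default_factory=dict)
    dihedral_coeffs: dict = field(default_factory=dict)
    scale14: tuple = (1.0, 1.0)            # (LJ, Coulomb) 1-4 scaling
    mixing: str = "geometric"

    def mixed_lj(self, ti: int, tj: int) -> tuple[float, float]:
        ei, si = self.lj[ti]
        ej, sj = self.lj[tj]
        if self.mixing != "geometric":
            raise ValueError(f"unsupported mixing rule {self.mixing!r}")
        return math.sqrt(ei * ej), math.sqrt(si * sj)

    def validate_cutoffs(self, box: np.ndarray, check_coulomb: bool = True) -> None:
        half = 0.5 * float(np.min(box))
        if self.lj_cutoff >= half:
            raise ValueError(f"LJ cutoff {self.lj_cutoff} >= half box {half}")
        if check_coulomb and self.coulomb_cutoff >= half:
            raise ValueError(f"Coulomb cutoff {self.coulomb_cutoff} >= half box {half}")


def stitch_coefficients(epsilon: float, sigma: float, r_m: float) -> tuple[float, float, float]:
    """Quadratic coefficients matching the 12-6 LJ potential C²-smoothly at r_m.

    Solves the 3×3 linear system ``p(r_m) = u(r_m)``, ``p'(r_m) = u'(r_m)``,
    ``p''(r_m) = u''(r_m)`` for ``p(r) = p0 + p1 r + p2 r²``.
    """
    if not 0 < r_m < 2 ** (1 / 6) * sigma:
        raise ValueError("require 0 < r_m < 2^(1/6) sigma")
    s6 = (sigma / r_m) ** 6
    u = 4 * epsilon * (s6 * s6 - s6)
    du = 4 * epsilon * (-12 * s6 * s6 + 6 * s6) / r_m
    d2u = 4 * epsilon * (156 * s6 * s6 - 42 * s6) / r_m ** 2
    mat = np.array([
        [1.0, r_m, r_m ** 2],
        [0.0, 1.0, 2 * r_m],
        [0.0, 0.0, 2.0],
    ])
    p0, p1, p2 = np.linalg.solve(mat, np.array([u, du, d2u]))
    return float(p0), float(p1), float(p2)


def lj_pair_energy(r, epsilon: float, sigma: float, r_m: float, cutoff: float):
    """Core-softened LJ energy for a single pair parameter set.

    Quadratic for ``r < r_m``, plain 12-6 LJ up to the cutoff, zero beyond.
    Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    p0, p1, p2 = stitch_coefficients(epsilon, sigma, r_m)
    with np.errstate(divide="ignore", over="ignore"):
        s6 = (sigma / r) ** 6
        lj = 4 * epsilon * (s6 * s6 - s6)
    e = np.where(r < r_m, p0 + p1 * r + p2 * r * r, lj)
    e = np.where(r >= cutoff, 0.0, e)
    return e if e.ndim else float(e)


# ---------------------------------------------------------------------------
# Pair tables
# ---------------------------------------------------------------------------


@dataclass
class PairTable:
    """Precomputed per-pair parameters for all retained nonbonded pairs."""

    i: np.ndarray
    j: np.ndarray
    inter: np.ndarray          # True for intermolecular pairs
    a12: np.ndarray            # 4 ε σ^12 (1-4 scaling folded in)
    a6: np.ndarray             # 4 ε σ^6
    rm: np.ndarray
    p0: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    qq: np.ndarray             # k_C q_i q_j (1-4 scaling folded in)
    self_energy: float         # Wolf self term (configuration independent)
    has_coulomb: bool

    @property
    def n_pairs(self) -> int:
        return len(self.i)


def _bonded_neighbour_shells(n_sites: int, bonds: np.ndarray):
    """Sets of (i, j) pairs separated by 1, 2 and 3 bonds (i < j)."""
    adj = [[] for _ in range(n_sites)]
    for _, i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    shells = {1: set(), 2: set(), 3: set()}
    for start in range(n_sites):
        dist = {start: 0}
        dq = deque([start])
        while dq:
            u = dq.popleft()
            if dist[u] == 3:
                continue
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    dq.append(v)
                    if start < v:
                        shells[dist[v]].add((start, v))
    return shells


def wolf_self_energy(charges: np.ndarray, alpha: float, rc: float, coulomb_const: float) -> float:
    """Standard Wolf self term: −k_C (erfc(αR_c)/(2R_c) + α/√π) Σ q_i²."""
    q2 = float(np.sum(np.asarray(charges) ** 2))
    if q2 == 0.0:
        return 0.0
    return -coulomb_const * (erfc(alpha * rc) / (2 * rc) + alpha / SQRT_PI) * q2


def build_pair_table(crystal: Crystal, ff: ForceField) -> PairTable:
    """Enumerate all retained nonbonded site pairs with mixed parameters."""
    n = crystal.n_sites
    i, j = np.triu_indices(n, k=1)
    inter = crystal.molecule[i] != crystal.molecule[j]

    shells = _bonded_neighbour_shells(n, crystal.bonds)
    excluded = shells[1] | shells[2]
    scaled14 = shells[3]
    if excluded:
        keep = np.array([(a, b) not in excluded for a, b in zip(i, j)])
        i, j, inter = i[keep], j[keep], inter[keep]

    lj_scale = np.ones(len(i))
    q_scale = np.ones(len(i))
    if scaled14 and (ff.scale14[0] != 1.0 or ff.scale14[1] != 1.0):
        is14 = np.array([(a, b) in scaled14 for a, b in zip(i, j)])
        lj_scale[is14] = ff.scale14[0]
        q_scale[is14] = ff.scale14[1]

    # per-type-pair mixed parameters
    ntypes = crystal.n_types
    eps_m = np.zeros((ntypes, ntypes))
    sig_m = np.zeros((ntypes, ntypes))
    for ta in range(ntypes):
        for tb in range(ntypes):
            eps_m[ta, tb], sig_m[ta, tb] = ff.mixed_lj(ta, tb)
    rm_m = ff.r_m_fraction * sig_m
    p0_m = np.zeros_like(eps_m)
    p1_m = np.zeros_like(eps_m)
    p2_m = np.zeros_like(eps_m)
    for ta in range(ntypes):
        for tb in range(ntypes):
            if eps_m[ta, tb] > 0 and rm_m[ta, tb] > 0:
                p0_m[ta, tb], p1_m[ta, tb], p2_m[ta, tb] = stitch_coefficients(
                    eps_m[ta, tb], sig_m[ta, tb], rm_m[ta, tb])

    ti, tj = crystal.types[i], crystal.types[j]
    eps = eps_m[ti, tj] * lj_scale
    sig = sig_m[ti, tj]
    qq = ff.units.coulomb * crystal.charges[i] * crystal.charges[j] * q_scale
    has_coulomb = bool(np.any(qq != 0.0))

    self_e = wolf_self_energy(crystal.charges, ff.wolf_alpha, ff.coulomb_cutoff,
                              ff.units.coulomb) if has_coulomb else 0.0

    return PairTable(
        i=i, j=j, inter=inter,
        a12=4 * eps * sig ** 12,
        a6=4 * eps * sig ** 6,
        rm=rm_m[ti, tj],
        p0=p0_m[ti, tj] * lj_scale,
        p1=p1_m[ti, tj] * lj_scale,
        p2=p2_m[ti, tj] * lj_scale,
        qq=qq,
        self_energy=self_e,
        has_coulomb=has_coulomb,
    )


# ---------------------------------------------------------------------------
# Vectorised pair terms
# ---------------------------------------------------------------------------


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.rint(d / box)


def _lj_terms(r, table, cutoff):
    """Per-pair core-softened LJ energy and radial derivative dU/dr.

    Overflow at vanishing separations is deliberately allowed to propagate
    as inf/nan so that the caller can abort with a diagnostic.
    """
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        inv_r = 1.0 / r
        inv6 = inv_r ** 6
        inv12 = inv6 * inv6
        e = table.a12 * inv12 - table.a6 * inv6
        dudr = (-12 * table.a12 * inv12 + 6 * table.a6 * inv6) * inv_r
    core = r < table.rm
    if np.any(core):
        e = np.where(core, table.p0 + table.p1 * r + table.p2 * r * r, e)
        dudr = np.where(core, table.p1 + 2 * table.p2 * r, dudr)
    outside = r >= cutoff
    e = np.where(outside, 0.0, e)
    dudr = np.where(outside, 0.0, dudr)
    return e, dudr


def _coulomb_terms(r, qq, alpha, rc, variant):
    """Per-pair Wolf energy and radial derivative dU/dr (no self term)."""
    inv_r = 1.0 / r
    damped = erfc(alpha * r) * inv_r
    gauss = 2 * alpha / SQRT_PI * np.exp(-(alpha * r) ** 2)
    shift = erfc(alpha * rc) / rc
    if variant == "energy_shifted":
        e = qq * (damped - shift)
        dudr = qq * (-(damped + gauss) * inv_r)
    elif variant == "force_shifted":
        fshift = shift / rc + 2 * alpha / SQRT_PI * math.exp(-(alpha * rc) ** 2) / rc
        e = qq * (damped - shift + fshift * (r - rc))
        dudr = qq * (-(damped + gauss) * inv_r + fshift)
    else:
        raise ValueError(f"unknown Wolf variant {variant!r}")
    outside = r >= rc
    e = np.where(outside, 0.0, e)
    dudr = np.where(outside, 0.0, dudr)
    return e, dudr


def wolf_energy(crystal: Crystal, charges: np.ndarray, alpha: float, rc: float,
                pair_mask=None, include_self: bool = True,
                variant: str = "energy_shifted",
                coulomb_const: float | None = None) -> float:
    """Total Wolf electrostatic energy of a configuration.

    ``pair_mask`` (boolean over the i<j pair list) restricts which pairs
    contribute to the pairwise part; the self term is configuration
    independent and never masked.
    """
    if rc >= 0.5 * float(np.min(crystal.box)):
        raise ValueError("Wolf cutoff must be below half the smallest box length")
    kc = crystal  # alias for brevity
    cc = REAL.coulomb if coulomb_const is None else coulomb_const
    charges = np.asarray(charges, dtype=float)
    i, j = np.triu_indices(kc.n_sites, k=1)
    if pair_mask is not None:
        i, j = i[pair_mask], j[pair_mask]
    d = minimum_image(kc.positions[j] - kc.positions[i], kc.box)
    r = np.linalg.norm(d, axis=1)
    qq = cc * charges[i] * charges[j]
    e, _ = _coulomb_terms(r, qq, alpha, rc, variant)
    total = float(e.sum())
    if include_self:
        total += wolf_self_energy(charges, alpha, rc, cc)
    return total


# ---------------------------------------------------------------------------
# Full evaluation
# ---------------------------------------------------------------------------


@dataclass
class EnergyReport:
    """Decomposed potential energy of one configuration.

    Intermolecular terms are split into crossing/non-crossing according to
    the mask supplied by the cleaving module (everything is "non-crossing"
    for a plain bulk evaluation).  ``forces`` include the coupling factor
    applied to crossing pairs.
    """

    u_lj_cross: float = 0.0
    u_c_cross: float = 0.0
    u_lj_noncross: float = 0.0
    u_c_noncross: float = 0.0
    u_intra_nb: float = 0.0
    u_self: float = 0.0
    u_bond: float = 0.0
    u_angle: float = 0.0
    u_dihedral: float = 0.0
    forces: np.ndarray | None = None
    virial: np.ndarray | None = None
    f_lambda: float = 1.0

    @property
    def u_cross(self) -> float:
        return self.u_lj_cross + self.u_c_cross

    @property
    def u_noncross(self) -> float:
        """Unscaled intermolecular energy (includes the Wolf self term)."""
        return self.u_lj_noncross + self.u_c_noncross + self.u_self

    @property
    def u_intra(self) -> float:
        return self.u_bond + self.u_angle + self.u_dihedral + self.u_intra_nb

    @property
    def u_total(self) -> float:
        return self.u_noncross + self.f_lambda * self.u_cross + self.u_intra


def evaluate(positions: np.ndarray, crystal: Crystal, ff: ForceField,
             table: PairTable, crossing: np.ndarray | None = None,
             f_lambda: float = 1.0, need_forces: bool = True) -> EnergyReport:
    """Evaluate all energy terms (and forces) for one configuration.

    ``crossing`` is a boolean array over the table's pair list marking the
    intermolecular pairs whose interaction is scaled by ``f_lambda``.
    """
    box = crystal.box
    rep = EnergyReport(f_lambda=f_lambda, u_self=table.self_energy)

    d = minimum_image(positions[table.j] - positions[table.i], box)
    r = np.linalg.norm(d, axis=1)
    e_lj, dudr_lj = _lj_terms(r, table, ff.lj_cutoff)
    if table.has_coulomb:
        e_c, dudr_c = _coulomb_terms(r, table.qq, ff.wolf_alpha,
                                     ff.coulomb_cutoff, ff.wolf_variant)
    else:
        e_c = dudr_c = np.zeros_like(r)

    inter = table.inter
    if crossing is None:
        crossing = np.zeros(table.n_pairs, dtype=bool)
    cross = crossing & inter
    noncross = inter & ~cross
    intra = ~inter

    rep.u_lj_cross = float(e_lj[cross].sum())
    rep.u_c_cross = float(e_c[cross].sum())
    rep.u_lj_noncross = float(e_lj[noncross].sum())
    rep.u_c_noncross = float(e_c[noncross].sum())
    rep.u_intra_nb = float(e_lj[intra].sum() + e_c[intra].sum())

    n = len(positions)
    forces = np.zeros((n, 3)) if need_forces else None
    virial = np.zeros(3)
    scale = np.where(cross, f_lambda, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = -scale * (dudr_lj + dudr_c) / r      # force on j along +d
    if need_forces or True:
        fvec = coef[:, None] * d
        virial += np.sum(coef[:, None] * d * d, axis=0)
        if need_forces:
            for ax in range(3):
                forces[:, ax] += np.bincount(table.j, weights=fvec[:, ax], minlength=n)
                forces[:, ax] -= np.bincount(table.i, weights=fvec[:, ax], minlength=n)

    b_e, b_forces, b_virial = _bonded(positions, box, crystal, ff, need_forces)
    rep.u_bond, rep.u_angle, rep.u_dihedral = b_e
    if need_forces:
        forces += b_forces
    virial += b_virial

    rep.forces = forces
    rep.virial = virial
    if not np.isfinite(rep.u_total):
        k = int(np.argmin(r))
        raise FloatingPointError(
            f"non-finite potential energy; closest pair "
            f"({table.i[k]}, {table.j[k]}) at r = {r[k]:.4g}"
        )
    return rep


def total_energy_forces(positions, crystal, ff, table=None):
    """Plain bulk energy and forces (no cleaving coupling)."""
    if table is None:
        table = build_pair_table(crystal, ff)
    rep = evaluate(positions, crystal, ff, table)
    return rep.u_total, rep.forces


def potential_energy(crystal: Crystal, ff: ForceField) -> float:
    rep = evaluate(crystal.positions, crystal, ff, build_pair_table(crystal, ff),
                   need_forces=False)
    return rep.u_total


# ---------------------------------------------------------------------------
# Bonded terms
# ---------------------------------------------------------------------------


def _bonded(positions, box, crystal, ff, need_forces):
    n = len(positions)
    forces = np.zeros((n, 3)) if need_forces else None
    virial = np.zeros(3)
    e_bond = e_angle = e_dihedral = 0.0

    if crystal.bonds.size:
        bt, bi, bj = crystal.bonds[:, 0], crystal.bonds[:, 1], crystal.bonds[:, 2]
        kb = np.array([ff.bond_coeffs[t][0] for t in bt])
        r0 = np.array([ff.bond_coeffs[t][1] for t in bt])
        d = minimum_image(positions[bj] - positions[bi], box)
        r = np.linalg.norm(d, axis=1)
        if np.any(r < 1e-10):
            raise ValueError("bond between coincident sites")
        e_bond = float(np.sum(0.5 * kb * (r - r0) ** 2))
        dudr = kb * (r - r0)
        coef = -dudr / r
        fvec = coef[:, None] * d
        virial += np.sum(coef[:, None] * d * d, axis=0)
        if need_forces:
            for ax in range(3):
                forces[:, ax] += np.bincount(bj, weights=fvec[:, ax], minlength=n)
                forces[:, ax] -= np.bincount(bi, weights=fvec[:, ax], minlength=n)

    if crystal.angles.size:
        at = crystal.angles[:, 0]
        ai, aj, ak = crystal.angles[:, 1], crystal.angles[:, 2], crystal.angles[:, 3]
        ka = np.array([ff.angle_coeffs[t][0] for t in at])
        th0 = np.array([ff.angle_coeffs[t][1] for t in at])
        u = minimum_image(positions[ai] - positions[aj], box)
        v = minimum_image(positions[ak] - positions[aj], box)
        ru = np.linalg.norm(u, axis=1)
        rv = np.linalg.norm(v, axis=1)
        if np.any(ru < 1e-10) or np.any(rv < 1e-10):
            raise ValueError("angle term between coincident sites")
        cth = np.clip(np.sum(u * v, axis=1) / (ru * rv), -1.0, 1.0)
        theta = np.arccos(cth)
        e_angle = float(np.sum(0.5 * ka * (theta - th0) ** 2))
        if need_forces:
            sth = np.sqrt(np.clip(1.0 - cth ** 2, 1e-14, None))
            dedth = ka * (theta - th0)
            # dθ/dr = −(1/sinθ)·dcosθ/dr
            coef = dedth / sth
            dc_di = (v / rv[:, None] - cth[:, None] * u / ru[:, None]) / ru[:, None]
            dc_dk = (u / ru[:, None] - cth[:, None] * v / rv[:, None]) / rv[:, None]
            f_i = coef[:, None] * dc_di
            f_k = coef[:, None] * dc_dk
            f_j = -(f_i + f_k)
            for ax in range(3):
                forces[:, ax] += np.bincount(ai, weights=f_i[:, ax], minlength=n)
                forces[:, ax] += np.bincount(aj, weights=f_j[:, ax], minlength=n)
                forces[:, ax] += np.bincount(ak, weights=f_k[:, ax], minlength=n)
            virial += np.sum(f_i * u + f_k * v, axis=0)

    if crystal.dihedrals.size:
        dt = crystal.dihedrals[:, 0]
        di, dj, dk, dl = (crystal.dihedrals[:, 1], crystal.dihedrals[:, 2],
                          crystal.dihedrals[:, 3], crystal.dihedrals[:, 4])
        kd = np.array([ff.dihedral_coeffs[t][0] for t in dt])
        mm = np.array([ff.dihedral_coeffs[t][1] for t in dt])
        dd = np.array([ff.dihedral_coeffs[t][2] for t in dt])
        b1 = minimum_image(positions[dj] - positions[di], box)
        b2 = minimum_image(positions[dk] - positions[dj], box)
        b3 = minimum_image(positions[dl] - positions[dk], box)
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        b2n = np.linalg.norm(b2, axis=1)
        x = np.sum(n1 * n2, axis=1)
        y = np.sum(np.cross(n1, n2) * b2 / b2n[:, None], axis=1)
        phi = np.arctan2(y, x)
        e_dihedral = float(np.sum(kd * (1.0 + np.cos(mm * phi - dd))))
        if need_forces:
            dedphi = -kd * mm * np.sin(mm * phi - dd)
            n1sq = np.sum(n1 * n1, axis=1)
            n2sq = np.sum(n2 * n2, axis=1)
            dphi_di = -(b2n / n1sq)[:, None] * n1
            dphi_dl = (b2n / n2sq)[:, None] * n2
            t = (np.sum(b1 * b2, axis=1) / b2n ** 2)[:, None]
            s = (np.sum(b3 * b2, axis=1) / b2n ** 2)[:, None]
            dphi_dj = -(1.0 + t) * dphi_di + s * dphi_dl
            dphi_dk = t * dphi_di - (1.0 + s) * dphi_dl
            f_i = -dedphi[:, None] * dphi_di
            f_j = -dedphi[:, None] * dphi_dj
            f_k = -dedphi[:, None] * dphi_dk
            f_l = -dedphi[:, None] * dphi_dl
            for ax in range(3):
                forces[:, ax] += np.bincount(di, weights=f_i[:, ax], minlength=n)
                forces[:, ax] += np.bincount(dj, weights=f_j[:, ax], minlength=n)
                forces[:, ax] += np.bincount(dk, weights=f_k[:, ax], minlength=n)
                forces[:, ax] += np.bincount(dl, weights=f_l[:, ax], minlength=n)
            # virial from forces and positions relative to site i of each term
            virial += np.sum(f_j * b1, axis=0)
            virial += np.sum(f_k * (b1 + b2), axis=0)
            virial += np.sum(f_l * (b1 + b2 + b3), axis=0)

    return (e_bond, e_angle, e_dihedral), forces, virial


def bonded_energy(crystal: Crystal, ff: ForceField,
                  positions: np.ndarray | None = None):
    """Total bonded energy with a per-term breakdown dictionary."""
    pos = crystal.positions if positions is None else positions
    (eb, ea, ed), _, _ = _bonded(pos, crystal.box, crystal, ff, need_forces=False)
    return eb + ea + ed, {"bond": eb, "angle": ea, "dihedral": ed}
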