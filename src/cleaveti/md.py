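"""A small molecular-dynamics engine for the cleaving calculations.

Velocity-Verlet integration with a Nosé–Hoover chain (length 3) thermostat
for NVT sampling at fixed λ, and an anisotropic Berendsen-type barostat for
zero-pressure equilibration of the bulk crystal.  The barostat is a
relaxation scheme, not an exact-ensemble one: equilibrated box lengths are
its only product, and the production (cleaving) stage always runs NVT.

All-pairs evaluation is the default at the system sizes this package
targets; a cell-list pair generator is provided and must agree with the
all-pairs path to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import forcefield as ffmod
from .cleaving import CleavingSpec, coupled_energy
from .crystal import Crystal

NH_CHAIN = 3


class MDInstabilityError(RuntimeError):
    pass


@dataclass
class TrajectoryState:
    """Dynamic state carried between runs (positions, velocities, thermostat)."""

    positions: np.ndarray
    velocities: np.ndarray
    box: np.ndarray
    xi: np.ndarray = field(default_factory=lambda: np.zeros(NH_CHAIN))
    vxi: np.ndarray = field(default_factory=lambda: np.zeros(NH_CHAIN))
    step: int = 0
    seed: int = 0

    def copy(self) -> "TrajectoryState":
        return TrajectoryState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            box=self.box.copy(),
            xi=self.xi.copy(), vxi=self.vxi.copy(),
            step=self.step, seed=self.seed,
        )


def kinetic_temperature(velocities, masses, units, dof=None):
    if dof is None:
        dof = 3 * len(masses) - 3
    ke2 = units.mv2e * float(np.sum(masses[:, None] * velocities ** 2))
    return ke2 / (dof * units.kb)


def initialize_velocities(crystal: Crystal, temperature: float, seed: int,
                          units=None) -> TrajectoryState:
    """Maxwell–Boltzmann velocities at the target temperature.

    Net linear momentum is removed and the kinetic temperature rescaled to
    the exact target (zero temperature gives zero velocities).  Deterministic
    for a given seed.
    """
    if units is None:
        from .units import REAL
        units = REAL
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    n = crystal.n_sites
    if temperature == 0.0:
        v = np.zeros((n, 3))
    else:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(units.kb * temperature / (crystal.masses * units.mv2e))
        v = rng.standard_normal((n, 3)) * sigma[:, None]
        # remove centre-of-mass drift, then rescale to the exact target
        p = np.sum(crystal.masses[:, None] * v, axis=0)
        v -= p / crystal.masses.sum()
        t_now = kinetic_temperature(v, crystal.masses, units)
        if t_now > 0:
            v *= np.sqrt(temperature / t_now)
    return TrajectoryState(
        positions=crystal.positions.copy(),
        velocities=v,
        box=crystal.box.copy(),
        seed=seed,
    )


def _nhc_half(vel, masses, dt, kt, dof, q, xi, vxi, mv2e):
    """Half-step Nosé–Hoover chain update; scales velocities in place."""
    m = len(q)
    ke2 = mv2e * float(np.sum(masses[:, None] * vel ** 2))
    g = np.empty(m)
    g[0] = (ke2 - dof * kt) / q[0]
    for k in range(1, m):
        g[k] = (q[k - 1] * vxi[k - 1] ** 2 - kt) / q[k]
    dt2, dt4, dt8 = dt / 2, dt / 4, dt / 8
    vxi[m - 1] += g[m - 1] * dt4
    for k in range(m - 2, -1, -1):
        e = np.exp(-dt8 * vxi[k + 1])
        vxi[k] = (vxi[k] * e + g[k] * dt4) * e
    s = np.exp(-dt2 * vxi[0])
    vel *= s
    ke2 *= s * s
    xi += vxi * dt2
    g[0] = (ke2 - dof * kt) / q[0]
    for k in range(m - 1):
        e = np.exp(-dt8 * vxi[k + 1])
        vxi[k] = (vxi[k] * e + g[k] * dt4) * e
        g[k + 1] = (q[k] * vxi[k] ** 2 - kt) / q[k + 1]
    vxi[m - 1] += g[m - 1] * dt4


def _forces(crystal, ff, table, spec, positions):
    if spec is None:
        rep = ffmod.evaluate(positions, crystal, ff, table)
        return rep.u_total, rep.forces, rep.virial, 0.0, 0.0, 1.0
    ce = coupled_energy(crystal, ff, spec, positions=positions, table=table,
                        need_forces=True)
    return (ce.u_total, ce.forces, ce.virial,
            ce.u_cross_lj, ce.u_cross_c, ce.fprime)


def run_nvt(crystal: Crystal, ff: ffmod.ForceField, state: TrajectoryState,
            steps: int, dt: float, temperature: float | None = None,
            tau: float | None = 100.0, spec: CleavingSpec | None = None,
            stride: int = 10, table: ffmod.PairTable | None = None,
            collect: bool = True):
    """Integrate ``steps`` of NVT (or NVE when ``tau`` is None) dynamics.

    Returns the advanced state and a DataFrame of sampled scalars: step,
    temperature, total potential energy, the per-area TI integrand
    components E_LJ / E_C, and the raw work densities g_LJ / g_C
    (−U_cross/(2A)) they derive from.
    """
    units = ff.units
    if table is None:
        table = ffmod.build_pair_table(crystal, ff)
    masses = crystal.masses
    dof = 3 * crystal.n_sites - 3
    nvt = tau is not None
    if nvt and temperature is None:
        raise ValueError("NVT integration needs a target temperature")
    if nvt:
        kt = units.kb * temperature
        q = np.full(NH_CHAIN, kt * tau ** 2)
        q[0] *= dof

    pos = state.positions.copy()
    vel = state.velocities.copy()
    crystal = crystal.copy()
    crystal.box = state.box.copy()
    inv_m = 1.0 / (masses[:, None] * units.mv2e)
    area2 = 2.0 * spec.area(crystal.box) if spec is not None else 1.0

    def forces_or_abort(pos, istep):
        try:
            return _forces(crystal, ff, table, spec, pos)
        except FloatingPointError as err:
            lam = spec.lam if spec is not None else 1.0
            raise MDInstabilityError(
                f"energy blow-up at step {istep}, lambda={lam}: {err}") from err

    u, forces, _, ucl, ucc, fp = forces_or_abort(pos, state.step)
    records = []

    def sample(istep, u, ucl, ucc, fp):
        t_inst = kinetic_temperature(vel, masses, units, dof)
        g_lj = -ucl / area2
        g_c = -ucc / area2
        records.append((istep, t_inst, u, fp * g_lj, fp * g_c, g_lj, g_c))

    for istep in range(steps):
        if nvt:
            _nhc_half(vel, masses, dt, kt, dof, q, state.xi, state.vxi, units.mv2e)
        vel += 0.5 * dt * forces * inv_m
        pos = np.mod(pos + dt * vel, crystal.box)
        u, forces, _, ucl, ucc, fp = forces_or_abort(pos, state.step + istep + 1)
        vel += 0.5 * dt * forces * inv_m
        if nvt:
            _nhc_half(vel, masses, dt, kt, dof, q, state.xi, state.vxi, units.mv2e)
        if collect and (istep + 1) % stride == 0:
            sample(state.step + istep + 1, u, ucl, ucc, fp)

    state = TrajectoryState(positions=pos, velocities=vel, box=crystal.box,
                            xi=state.xi, vxi=state.vxi,
                            step=state.step + steps, seed=state.seed)
    frame = pd.DataFrame(records,
                         columns=["step", "T", "U", "E_LJ", "E_C", "g_LJ", "g_C"])
    return state, frame


def total_energy(crystal, ff, state, spec=None, table=None):
    """Instantaneous total (kinetic + potential) energy of a state."""
    u, _, _, _, _, _ = _forces(crystal, ff,
                               table or ffmod.build_pair_table(crystal, ff),
                               spec, state.positions)
    ke = 0.5 * ff.units.mv2e * float(
        np.sum(crystal.masses[:, None] * state.velocities ** 2))
    return u + ke


def run_npt_equilibration(crystal: Crystal, ff: ffmod.ForceField,
                          state: TrajectoryState, steps: int, dt: float,
                          temperature: float, pressure: float = 0.0,
                          tau_t: float = 100.0, tau_p: float = 1000.0,
                          kappa: float | None = None, stride: int = 10):
    """Anisotropic zero-pressure equilibration of the bulk crystal.

    Each axis is rescaled independently by a Berendsen-type relaxation
    toward the target pressure (given in bar in real units).  Returns the
    advanced state plus tail-averaged box lengths with standard errors
    (second half of the sampled trajectory).
    """
    units = ff.units
    table = ffmod.build_pair_table(crystal, ff)
    masses = crystal.masses
    dof = 3 * crystal.n_sites - 3
    kt = units.kb * temperature
    q = np.full(NH_CHAIN, kt * tau_t ** 2)
    q[0] *= dof
    if kappa is None:
        # generic solid-like compressibility, in internal pressure units
        kappa = 1.0 if units.name == "reduced" else 4.5e-5 * units.pressure
    p_target = pressure / units.pressure   # internal units

    work = crystal.copy()
    work.box = state.box.copy()
    pos = state.positions.copy()
    vel = state.velocities.copy()
    box0 = state.box.copy()
    inv_m = 1.0 / (masses[:, None] * units.mv2e)

    u, forces, virial, *_ = _forces(work, ff, table, None, pos)
    box_samples = []
    for istep in range(steps):
        _nhc_half(vel, masses, dt, kt, dof, q, state.xi, state.vxi, units.mv2e)
        vel += 0.5 * dt * forces * inv_m
        pos = np.mod(pos + dt * vel, work.box)
        u, forces, virial, *_ = _forces(work, ff, table, None, pos)
        vel += 0.5 * dt * forces * inv_m
        _nhc_half(vel, masses, dt, kt, dof, q, state.xi, state.vxi, units.mv2e)

        ke2_axis = units.mv2e * np.sum(masses[:, None] * vel ** 2, axis=0)
        p_axis = (ke2_axis + virial) / work.volume
        mu = np.clip(1.0 - (dt * kappa / (3.0 * tau_p)) * (p_target - p_axis),
                     0.98, 1.02)
        work.box = work.box * mu
        pos = np.mod(pos * mu, work.box)
        if np.any(work.box > 2.0 * box0) or np.any(work.box < 0.5 * box0):
            raise MDInstabilityError(
                f"box collapsed/exploded during NPT at step {istep + 1}: "
                f"{work.box.tolist()}")
        if (istep + 1) % stride == 0:
            box_samples.append(work.box.copy())

    box_samples = np.array(box_samples)
    tail = box_samples[len(box_samples) // 2:]
    means = tail.mean(axis=0)
    stderr = tail.std(axis=0, ddof=1) / np.sqrt(len(tail)) if len(tail) > 1 \
        else np.zeros(3)
    state = TrajectoryState(positions=pos, velocities=vel, box=work.box,
                            xi=state.xi, vxi=state.vxi,
                            step=state.step + steps, seed=state.seed)
    return state, means, stderr


# ---------------------------------------------------------------------------
# Cell list
# ---------------------------------------------------------------------------


def cell_list_pairs(positions: np.ndarray, box: np.ndarray, cutoff: float):
    """Candidate i<j pairs within ``cutoff`` via a linked-cell sweep.

    Falls back to all pairs when the box is too small for 3 cells per axis.
    Returns sorted (i, j) index arrays containing every pair closer than the
    cutoff (possibly more).
    """
    n = len(positions)
    nbins = np.floor(box / cutoff).astype(int)
    if np.any(nbins < 3):
        return np.triu_indices(n, k=1)
    width = box / nbins
    cell = np.floor(np.mod(positions, box) / width).astype(int)
    cell = np.minimum(cell, nbins - 1)
    flat = (cell[:, 0] * nbins[1] + cell[:, 1]) * nbins[2] + cell[:, 2]
    order = np.argsort(flat, kind="stable")
    sorted_flat = flat[order]
    boundaries = np.searchsorted(sorted_flat,
                                 np.arange(np.prod(nbins) + 1))
    members = [order[boundaries[c]:boundaries[c + 1]]
               for c in range(np.prod(nbins))]

    offsets = [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
    out_i, out_j = [], []
    for cx in range(nbins[0]):
        for cy in range(nbins[1]):
            for cz in range(nbins[2]):
                home = members[(cx * nbins[1] + cy) * nbins[2] + cz]
                if len(home) == 0:
                    continue
                for dx, dy, dz in offsets:
                    nx_, ny_, nz_ = ((cx + dx) % nbins[0],
                                     (cy + dy) % nbins[1],
                                     (cz + dz) % nbins[2])
                    code = (nx_ * nbins[1] + ny_) * nbins[2] + nz_
                    other = members[code]
                    if len(other) == 0:
                        continue
                    ii = np.repeat(home, len(other))
                    jj = np.tile(other, len(home))
                    keep = ii < jj
                    out_i.append(ii[keep])
                    out_j.append(jj[keep])
    i = np.concatenate(out_i)
    j = np.concatenate(out_j)
    # the sweep sees each pair from both home cells: deduplicate
    codes = np.unique(i.astype(np.int64) * n + j)
    i, j = codes // n, codes % n
    d = positions[j] - positions[i]
    d -= box * np.rint(d / box)
    within = np.einsum("ij,ij->i", d, d) <= cutoff * cutoff
    return i[within], j[within]
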