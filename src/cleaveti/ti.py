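"""Thermodynamic-integration pipeline for the cleaving path.

The path runs from the bulk crystal (λ = 1) to the slab (λ = 0).  At each
λ the system is equilibrated and then sampled, inheriting the previous
endpoint configuration; the sampled quantity per component is the work
density

    g(λ) = −⟨U_cross⟩_λ / (2A),

so that the TI integrand is E(λ) = f'(λ)·g(λ) and the surface free energy
is γ = ∫₀¹ E dλ.  The quadrature integrates g against df = f'(λ)dλ with
the trapezoidal rule on the nodes u_k = f(λ_k): this is algebraically a
quadrature of E over λ, but it is exact whenever g is constant in λ —
in particular in frozen-configuration mode — and it is well conditioned
under the strong endpoint densification of the default schedule.

Per-λ standard errors come from Flyvbjerg–Petersen block averaging
(block doubling until the error estimate saturates) and are propagated
linearly through the quadrature weights, treating λ points as independent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import forcefield as ffmod
from .cleaving import CleavingSpec, coupled_energy, coupling
from .crystal import Crystal, make_vacuum_slab
from .md import TrajectoryState, initialize_velocities, run_nvt

log = logging.getLogger("cleaveti")


@dataclass
class LambdaSchedule:
    """Ordered λ values (1 → 0) and per-λ run lengths in MD steps."""

    lambdas: np.ndarray
    equil_steps: int = 200
    prod_steps: int = 600

    def __post_init__(self):
        lam = np.asarray(self.lambdas, dtype=float)
        if len(lam) < 3:
            raise ValueError("schedule needs at least 3 lambda values")
        if lam[0] != 1.0 or lam[-1] != 0.0:
            raise ValueError("schedule must run from lambda=1 to lambda=0")
        if not np.all(np.diff(lam) < 0):
            raise ValueError("schedule must be strictly decreasing")
        self.lambdas = lam

    @property
    def count(self) -> int:
        return len(self.lambdas)


def make_schedule(count: int = 45, densification: float = 2.0,
                  equil_steps: int = 200, prod_steps: int = 600) -> LambdaSchedule:
    """Symmetric λ grid densified toward both endpoints.

    Uses the stretched mapping λ_k = ½[1 + tanh(d·u_k)/tanh(d)] over a
    uniform grid u_k ∈ [−1, 1]; d = 0 recovers the uniform grid.  Returned
    in run order, 1 → 0.
    """
    if count < 3:
        raise ValueError("need at least 3 lambda values")
    u = np.linspace(-1.0, 1.0, count)
    if densification == 0.0:
        lam = 0.5 * (1.0 + u)
    else:
        d = float(densification)
        lam = 0.5 * (1.0 + np.tanh(d * u) / np.tanh(d))
    lam[0], lam[-1] = 0.0, 1.0
    return LambdaSchedule(lambdas=lam[::-1].copy(),
                          equil_steps=equil_steps, prod_steps=prod_steps)


def block_stderr(series: np.ndarray) -> float:
    """Standard error of the mean of a correlated series.

    Flyvbjerg–Petersen blocking: double the block length until fewer than
    8 blocks remain and take the largest (most conservative) estimate.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        return 0.0
    best = 0.0
    while len(x) >= 8:
        best = max(best, float(np.std(x, ddof=1) / np.sqrt(len(x))))
        if len(x) % 2:
            x = x[:-1]
        x = 0.5 * (x[0::2] + x[1::2])
    if len(x) >= 2:
        best = max(best, float(np.std(x, ddof=1) / np.sqrt(len(x))))
    return best


@dataclass
class TIResult:
    """Integrated surface free energy with its LJ/Coulomb decomposition.

    Per-λ series and γ values are in output units (mJ/m² in real units,
    ε/σ² in reduced units).  ``gamma == gamma_lj + gamma_c`` holds exactly
    by linearity of the quadrature.
    """

    lambdas: np.ndarray
    e_lj: np.ndarray           # integrand E_LJ(λ) = f'(λ) g_LJ(λ)
    e_c: np.ndarray
    g_lj: np.ndarray           # work densities −⟨U_cross⟩/(2A)
    g_c: np.ndarray
    se_lj: np.ndarray          # standard errors of g_LJ
    se_c: np.ndarray
    gamma_lj: float
    gamma_c: float
    gamma: float
    err_lj: float
    err_c: float
    err_total: float
    metadata: dict = field(default_factory=dict)

    def per_lambda_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lambda": self.lambdas,
            "E_LJ": self.e_lj, "E_C": self.e_c,
            "g_LJ": self.g_lj, "g_C": self.g_c,
            "stderr_LJ": self.se_lj, "stderr_C": self.se_c,
        })

    def to_dict(self) -> dict:
        return {
            "gamma_lj": self.gamma_lj, "gamma_c": self.gamma_c,
            "gamma": self.gamma,
            "err_lj": self.err_lj, "err_c": self.err_c,
            "err_total": self.err_total,
            "lambdas": self.lambdas.tolist(),
            "g_lj": self.g_lj.tolist(), "g_c": self.g_c.tolist(),
            "stderr_lj": self.se_lj.tolist(), "stderr_c": self.se_c.tolist(),
            "metadata": self.metadata,
        }


def _f_space_weights(lambdas: np.ndarray, n: int, form: str) -> np.ndarray:
    """Trapezoidal weights for ∫ g df on the nodes u_k = f(λ_k)."""
    lam = np.asarray(lambdas, dtype=float)
    order = np.argsort(lam)
    u = np.array([coupling(l, n, form)[0] for l in lam[order]])
    w_sorted = np.zeros(len(lam))
    du = np.diff(u)
    w_sorted[:-1] += 0.5 * du
    w_sorted[1:] += 0.5 * du
    weights = np.zeros(len(lam))
    weights[order] = w_sorted
    return weights


def integrate_and_decompose(lambdas, g_lj, g_c, se_lj=None, se_c=None,
                            n: int = 4, form: str = "power",
                            metadata: dict | None = None) -> TIResult:
    """Quadrature of the per-λ work densities into γ^LJ, γ^C and γ.

    ``g_lj``/``g_c`` are the per-λ mean work densities −⟨U_cross⟩/(2A) in
    output units; the components are integrated on the same grid, so
    additivity γ = γ^LJ + γ^C is exact.
    """
    lam = np.asarray(lambdas, dtype=float)
    if len(lam) < 3:
        raise ValueError("need at least 3 lambda points")
    g_lj = np.asarray(g_lj, dtype=float)
    g_c = np.asarray(g_c, dtype=float)
    se_lj = np.zeros_like(g_lj) if se_lj is None else np.asarray(se_lj, float)
    se_c = np.zeros_like(g_c) if se_c is None else np.asarray(se_c, float)
    w = _f_space_weights(lam, n, form)
    gamma_lj = float(w @ g_lj)
    gamma_c = float(w @ g_c)
    err_lj = float(np.sqrt(np.sum((w * se_lj) ** 2)))
    err_c = float(np.sqrt(np.sum((w * se_c) ** 2)))
    fprime = np.array([coupling(l, n, form)[1] for l in lam])
    return TIResult(
        lambdas=lam,
        e_lj=fprime * g_lj, e_c=fprime * g_c,
        g_lj=g_lj, g_c=g_c, se_lj=se_lj, se_c=se_c,
        gamma_lj=gamma_lj, gamma_c=gamma_c, gamma=gamma_lj + gamma_c,
        err_lj=err_lj, err_c=err_c,
        err_total=float(np.sqrt(err_lj ** 2 + err_c ** 2)),
        metadata=metadata or {},
    )


def forcefield_hash(ff: ffmod.ForceField) -> str:
    payload = json.dumps({
        "units": ff.units.name, "lj": {str(k): v for k, v in ff.lj.items()},
        "lj_cutoff": ff.lj_cutoff, "r_m_fraction": ff.r_m_fraction,
        "wolf_alpha": ff.wolf_alpha, "coulomb_cutoff": ff.coulomb_cutoff,
        "wolf_variant": ff.wolf_variant,
        "bonds": {str(k): list(v) for k, v in ff.bond_coeffs.items()},
        "angles": {str(k): list(v) for k, v in ff.angle_coeffs.items()},
        "dihedrals": {str(k): list(v) for k, v in ff.dihedral_coeffs.items()},
        "scale14": list(ff.scale14),
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_cleaving(crystal: Crystal, ff: ffmod.ForceField, spec: CleavingSpec,
                 schedule: LambdaSchedule, seed: int = 1,
                 temperature: float = 300.0, dt: float = 1.0,
                 tau: float = 100.0, stride: int = 5,
                 frozen: bool = False, pre_equil_steps: int | None = None,
                 state: TrajectoryState | None = None) -> TIResult:
    """Run the full cleaving path and integrate the surface free energy.

    Sequential protocol: for each λ from 1 to 0, equilibrate then sample
    the integrand; the last configuration seeds the next λ.  With
    ``frozen=True`` no dynamics is performed and the work density is a
    single exact evaluation per λ on the input configuration — used as an
    identity check of the quadrature, since then γ must equal
    (U_slab − U_bulk)/(2A) of that configuration exactly.
    """
    ff.validate_cutoffs(crystal.box, check_coulomb=bool(np.any(crystal.charges)))
    table = ffmod.build_pair_table(crystal, ff)
    area2 = 2.0 * spec.area(crystal.box)
    sfe_conv = ff.units.sfe
    n, form = spec.coupling_exponent, spec.coupling_form

    g_lj, g_c, se_lj, se_c = [], [], [], []
    if frozen:
        for lam in schedule.lambdas:
            ce = coupled_energy(crystal, ff, spec.at_lambda(lam), table=table)
            g_lj.append(-ce.u_cross_lj / area2 * sfe_conv)
            g_c.append(-ce.u_cross_c / area2 * sfe_conv)
            se_lj.append(0.0)
            se_c.append(0.0)
    else:
        if state is None:
            state = initialize_velocities(crystal, temperature, seed, ff.units)
            # thermalise the bulk before entering the path: the first λ points
            # otherwise sample a cold lattice and bias the integrand near λ=1
            n_pre = 5 * schedule.equil_steps if pre_equil_steps is None \
                else pre_equil_steps
            if n_pre:
                state, _ = run_nvt(crystal, ff, state, n_pre, dt,
                                   temperature, tau, spec=spec.at_lambda(1.0),
                                   table=table, collect=False)
        for lam in schedule.lambdas:
            spec_l = spec.at_lambda(lam)
            state, _ = run_nvt(crystal, ff, state, schedule.equil_steps, dt,
                               temperature, tau, spec=spec_l, table=table,
                               collect=False)
            state, frame = run_nvt(crystal, ff, state, schedule.prod_steps, dt,
                                   temperature, tau, spec=spec_l, table=table,
                                   stride=stride)
            gl = frame["g_LJ"].to_numpy() * sfe_conv
            gc = frame["g_C"].to_numpy() * sfe_conv
            g_lj.append(float(gl.mean()))
            g_c.append(float(gc.mean()))
            se_lj.append(block_stderr(gl))
            se_c.append(block_stderr(gc))
            log.info("lambda=%.5f  g_LJ=%.4f(%.4f)  g_C=%.4f(%.4f)",
                     lam, g_lj[-1], se_lj[-1], g_c[-1], se_c[-1])

    metadata = {
        "n": n, "coupling_form": form, "seed": seed,
        "temperature": temperature, "dt": dt, "tau": tau,
        "frozen": frozen, "schedule_count": schedule.count,
        "equil_steps": schedule.equil_steps, "prod_steps": schedule.prod_steps,
        "axis": spec.axis, "plane": spec.plane_position,
        "area": spec.area(crystal.box),
        "forcefield": forcefield_hash(ff),
        "units": ff.units.name,
    }
    return integrate_and_decompose(schedule.lambdas, g_lj, g_c, se_lj, se_c,
                                   n=n, form=form, metadata=metadata)


def static_sfe_oracle(crystal: Crystal, ff: ffmod.ForceField,
                      spec: CleavingSpec) -> float:
    """Static lattice-sum surface free energy of the frozen configuration.

    Independent of the cleaving mask: the slab endpoint is evaluated as a
    plain periodic system with vacuum padding wider than every cutoff along
    the cleaving normal, so γ₀ = (U_slab − U_bulk)/(2A).  Only valid when
    the cleaving plane sits at the periodic boundary (padding at that
    boundary separates exactly the interactions the mask would switch off).
    """
    if spec.plane_position != 0.0:
        raise ValueError("the vacuum-slab oracle requires the plane at the boundary")
    u_bulk = ffmod.potential_energy(crystal, ff)
    pad = 2.0 * max(ff.lj_cutoff, ff.coulomb_cutoff) + 2.0
    slab = make_vacuum_slab(crystal, axis=spec.axis, padding=pad)
    u_slab = ffmod.potential_energy(slab, ff)
    return (u_slab - u_bulk) / (2.0 * spec.area(crystal.box)) * ff.units.sfe
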