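"""Declarative run configuration (TOML).

A single config file describes the whole run so that results are
self-documenting: system source (data file or built-in fixture), force
field, cleaving geometry, λ schedule, MD settings, seed and unit system.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import forcefield as ffmod
from .cleaving import CleavingSpec
from .crystal import Crystal, generate_toy_crystal
from .ti import LambdaSchedule, make_schedule
from .units import get_units


@dataclass
class RunConfig:
    raw: dict
    path: Path | None = None

    # resolved objects
    crystal: Crystal | None = None
    forcefield: ffmod.ForceField | None = None
    spec: CleavingSpec | None = None
    schedule: LambdaSchedule | None = None
    md: dict = field(default_factory=dict)
    seed: int = 1

    @property
    def hash(self) -> str:
        payload = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = RunConfig(raw=raw, path=path)

    units = get_units(raw.get("units", {}).get("system", "real"))

    system = raw.get("system", {})
    if "fixture" in system:
        reps = tuple(system.get("reps", [3, 3, 3]))
        crystal, ff = generate_toy_crystal(system["fixture"], reps,
                                           seed=system.get("seed", 0))
    elif "data_file" in system:
        from .lammps_io import read_lammps_data
        data_path = Path(system["data_file"])
        if not data_path.is_absolute():
            data_path = path.parent / data_path
        if not data_path.exists():
            raise FileNotFoundError(f"data file not found: {data_path}")
        crystal, ff = read_lammps_data(data_path)
        ff.units = units
    else:
        raise ValueError("config [system] needs either 'fixture' or 'data_file'")

    ffsec = raw.get("forcefield", {})
    if "lj" in ffsec:
        ff.lj = {int(k): tuple(v) for k, v in ffsec["lj"].items()}
    for key in ("lj_cutoff", "r_m_fraction", "wolf_alpha", "coulomb_cutoff",
                "wolf_variant", "mixing"):
        if key in ffsec:
            setattr(ff, key, ffsec[key])
    if "scale14" in ffsec:
        ff.scale14 = tuple(ffsec["scale14"])
    for sec, attr in (("bonds", "bond_coeffs"), ("angles", "angle_coeffs"),
                      ("dihedrals", "dihedral_coeffs")):
        if sec in ffsec:
            table = {int(k): tuple(v) for k, v in ffsec[sec].items()}
            setattr(ff, attr, table)
    ff.validate_cutoffs(crystal.box)

    clv = raw.get("cleaving", {})
    plane = clv.get("plane", "boundary")
    spec = CleavingSpec(
        normal_axis=clv.get("axis", "z"),
        plane_position=0.0 if plane == "boundary" else float(plane),
        coupling_exponent=int(clv.get("n", 4)),
        coupling_form=clv.get("form", "power"),
    )

    sch = raw.get("schedule", {})
    schedule = make_schedule(
        count=int(sch.get("count", 45)),
        densification=float(sch.get("densification", 2.0)),
        equil_steps=int(sch.get("equil_steps", 200)),
        prod_steps=int(sch.get("prod_steps", 600)),
    )

    md = dict(raw.get("md", {}))
    md.setdefault("temperature", 300.0 if units.name == "real" else 0.1)
    md.setdefault("dt", 1.0 if units.name == "real" else 0.004)
    md.setdefault("tau", 100.0 * md["dt"] if units.name == "reduced" else 100.0)
    md.setdefault("stride", 5)

    cfg.crystal = crystal
    cfg.forcefield = ff
    cfg.spec = spec
    cfg.schedule = schedule
    cfg.md = md
    cfg.seed = int(raw.get("seed", 1))
    return cfg
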