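# Methods

## The cleaving path

`cleaveti` computes the surface free energy (SFE) γ of a crystal as the
reversible work, per unit area, of creating two free surfaces from the bulk.
The thermodynamic path connects the fully periodic bulk crystal (λ = 1) to a
slab (λ = 0) that no longer interacts with its periodic images along one box
axis.  A cleaving plane is placed in an inter-layer gap — by default at the
periodic boundary of the chosen axis — and every *intermolecular* site pair
whose minimum-image interaction path passes through that plane has its
interaction scaled by a coupling function f(λ):

    U(λ) = U_noncross + f(λ) · U_cross + U_intra,
    f(1) = 1,  f(0) = 0.

This is algebraically identical to f·U_bulk + (1 − f)·U_slab + U_intra.
Intramolecular terms (bonds, angles, dihedrals, and 1-4+ nonbonded pairs) are
never scaled: molecules stay intact while the crystal is cleaved.  No
restraining wall is used; the method relies on the premise that at the
temperatures of interest molecules do not leave the lattice, which holds for
every fixture shipped with the package (a diagnostic warns if a molecule ever
straddles the plane).

The SFE follows from thermodynamic integration,

    γ = −(1/2A) ∫₀¹ f'(λ) ⟨U_cross⟩_λ dλ = ∫₀¹ E(λ) dλ,

where A is the area of one created surface (2A of new surface is created)
and E(λ) = f'(λ)·g(λ) with the work density g(λ) = −⟨U_cross⟩_λ/(2A).
Because U_cross splits exactly into Lennard-Jones and Coulomb parts, γ
decomposes as γ = γ^LJ + γ^C, integrated per component on the same grid, so
the additivity is exact by construction.

The default coupling is f(λ) = λⁿ with n = 4.  Only the endpoint values and
the role of the exponent are constrained physically; a normalized-ratio form
λⁿ/(λⁿ + (1−λ)ⁿ) is selectable, and a consistency test requires γ to be
independent of n within statistical error.  A high exponent makes f'(0) = 0,
which suppresses the LJ endpoint catastrophe: near λ = 0 weakly repelled
sites may approach the steep r⁻¹² core and destabilise the dynamics.

As a second safeguard the LJ potential is replaced below r_m = 0.5 σ by a
quadratic p0 + p1 r + p2 r², with coefficients fixed by matching value, slope
and curvature of the 12-6 form at r_m (a 3×3 linear solve per type pair).
With r_m this small, fully coupled states never sample r < r_m, so the end
states — and therefore the reversible work — are unaffected.

## Energy model

* **LJ**: 12-6 with the quadratic core described above, geometric mixing for
  both ε and σ, plain truncation at the cutoff (no tail corrections: a
  system with surfaces violates the homogeneity assumption behind them).
* **Electrostatics**: Wolf summation — a damped (erfc), cutoff, energy-shifted
  pairwise sum plus the standard configuration-independent self term
  −k_C(erfc(αR_c)/2R_c + α/√π)Σq².  The pairwise energy vanishes continuously
  at R_c; forces are the exact gradient of this energy.  A damped-shifted-force
  variant (forces also continuous at R_c) is available via
  `wolf_variant="force_shifted"`.  The self term is assigned to the unscaled
  part of the potential: it is configuration-independent and cancels in
  U_bulk − U_slab.  Validation is against a brute-force minimum-image direct
  sum on a rock-salt lattice (agreement well under 1% per ion, both close to
  the Madelung limit).
* **Bonded**: harmonic bonds ½k(r−r₀)², harmonic angles ½k(θ−θ₀)², periodic
  dihedrals k[1 + cos(mφ − δ)].  1-2 and 1-3 nonbonded pairs are excluded,
  1-4 pairs included (scaling configurable).
* **Units**: internally kJ/mol, Å, fs, K, e with k_C = 138.935458
  kJ·mol⁻¹·Å·e⁻²; γ is reported in mJ/m² (1 kJ·mol⁻¹·Å⁻² = 166.054 mJ/m²).
  A reduced LJ unit system (ε = σ = m = k_B = 1) serves the atomic fixtures.

Every force routine is held to a central-difference check at 1e-6 relative
tolerance, and the λ-coupled decomposition is checked against two
independent identities: U(λ) = f·U_bulk + (1−f)·U_slab evaluated from two
full endpoint calculations, and the λ = 0 endpoint against a plain periodic
evaluation of the same configuration in a vacuum-padded box wider than every
cutoff.  The vacuum-padded route is also the *static lattice-sum oracle*
γ₀ = (U_slab − U_bulk)/(2A) used to validate the full dynamical TI in the
T → 0 limit.

## Sampling protocol

The λ grid runs 1 → 0 with 45 points by default, densified toward both
endpoints by the stretched mapping λ_k = ½[1 + tanh(d·u_k)/tanh(d)] over a
uniform u_k ∈ [−1, 1] (d = 2 by default; d = 0 gives a uniform grid).  Each
λ inherits the final configuration of the previous one, is equilibrated, and
then sampled.  Before the first λ point the bulk is thermalised at λ = 1
(default: five equilibration blocks); without this the early integrand
samples reflect a cold lattice and bias γ by a few tenths of a percent, with
a weight that depends on the coupling exponent.

Dynamics are velocity-Verlet with a Nosé–Hoover chain of length 3 (chains
rather than a single thermostat for ergodicity on small fixtures; coupling
time 100 timesteps by default).  NVE runs (thermostat off) conserve energy
to better than 1e-4 relative over 10⁴ steps on the LJ fixture and conserve
momentum to ~1e-10.  For bulk equilibration an anisotropic Berendsen-type
barostat relaxes each box length independently toward the target pressure;
it is a relaxation scheme, not ensemble-exact, and only supplies averaged
box lengths to the NVT cleaving stage.

**Quadrature.** γ = ∫ g df is evaluated by the trapezoidal rule on the nodes
u_k = f(λ_k).  This is exact whenever g is constant in λ — in particular in
frozen-configuration mode, where the identity γ = (U_slab − U_bulk)/(2A)
must hold to quadrature precision (observed: machine precision) — and for
smooth thermal integrands its discretisation error on the 45-point grid is
below 1e-4 relative, an order of magnitude under the statistical errors at
fixture scale.  Simpson integration would need a uniform grid and is not
used with the densified default.

**Errors.** Per-λ standard errors come from Flyvbjerg–Petersen blocking
(block doubling, the largest estimate across levels with ≥ 8 blocks) and are
propagated linearly through the quadrature weights, treating λ points as
independent.  Because consecutive λ points inherit configurations, slow
collective modes can correlate neighbouring means; the quoted errors are
therefore mild underestimates of the true run-to-run spread (observed factor
≈ 2 on the smallest fixture).  Replicate runs with different seeds are the
robust way to bound this.

## Toy crystals

The package is validated on three built-in, fully deterministic fixtures
(the `seed` argument is recorded but no randomness is used in construction):

* `lj_fcc` — 108-site Lennard-Jones fcc solid in reduced units.  The lattice
  constant minimises the truncated-potential energy (a ≈ 1.5566 σ at
  r_c = 2 σ); the cutoff is placed in a gap between coordination shells so
  truncation noise at low temperature is minimal.
* `diatomic_molecular` — rock-salt arrangement of ±0.3 e dumbbells joined by
  stiff harmonic bonds (real units).  The nearest-neighbour spacing
  minimises the lattice energy; because the bonded partner is excluded from
  nonbonded interactions on one side only, the ideal lattice is not exactly
  force-free and the structure is relaxed to the nearby minimum.
* `flexible_chain` — tetragonal crystal of 4-site zig-zag chains with bonds,
  angles, one dihedral and alternating ±0.12 e charges, relaxed with FIRE.
  FIRE is used instead of a line-search minimiser because the truncated LJ
  energy is discontinuous at the cutoff, which defeats line searches while
  leaving forces well-defined.

All basis lattices are offset by a quarter cell so that periodic boundaries
fall in inter-layer gaps: a cleaving plane must never cut through an atomic
layer (a site exactly on the plane makes the crossing classification
ambiguous and breaks the equivalence with the vacuum-slab route).

Every fixture satisfies max |force| < 1e-6 internal units at construction,
so TI paths start from genuine lattices.

What the fixtures do *not* emulate: real molecular crystals have many site
types, competing polymorphs, slow librational modes and long-range
electrostatic anisotropy.  Passing fixture tests therefore demonstrates the
correctness of the machinery (masking, coupling, quadrature, thermostats,
error propagation), not force-field fidelity for any specific material.

## Default study conditions at fixture scale

* Frozen-configuration identity: 45-point grid, n ∈ {2, 3, 4}, both atomic
  and molecular fixtures; agreement with the direct energy difference to
  better than 1e-6 relative (observed ~1e-15).
* T → 0 validation: `lj_fcc` at T = 0.01 ε/k_B, dt = 0.004 τ_LJ, 200 + 600
  steps per λ.  The dynamical γ agrees with the static oracle to ≈ 0.7%;
  the residual difference is genuine surface relaxation, which the TI path
  includes and the unrelaxed lattice sum does not.
* Coupling-exponent consistency: T = 0.15 ε/k_B, 1000 + 1200 steps per λ.
  This temperature is warm enough that within-λ statistics dominate the
  small protocol biases, yet cold enough that irreversible surface
  rearrangements (observed occasionally at T = 0.2) do not occur.  The
  per-λ equilibration length matters here: with ~300-step equilibration a
  lag bias of ~0.2% appears with an n-dependent weight; at 1000 steps γ for
  n = 2, 3, 4 agrees within ~1σ.
* Full-protocol lengths (e.g. the 100 ps + 500 ps per λ typical of
  production molecular-crystal studies) remain available through the
  configuration file; the defaults above are chosen so the whole validation
  suite runs on a single CPU core in minutes.

## Known limitations

* Orthorhombic boxes only; no symmetry expansion of unit cells (cells are
  explicit site lists).
* No Ewald/PPPM electrostatics; Wolf summation is the only long-range model,
  validated against direct summation on ionic toys.
* The Berendsen-type barostat is not ensemble-exact; NPT output is used only
  to fix box lengths for NVT production.
* Single-step solid–vacuum cleaving only: no liquid phase, hence no
  crystal–liquid interfacial free energies.
* Error bars assume independent λ points (see above).
* Percent-style report rounding follows the convention of quoting whole
  percent; the underlying values are never rounded until report time.
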