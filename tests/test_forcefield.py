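"""Energy terms: core-softened LJ, Wolf electrostatics, bonded interactions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import erfc

import cleaveti as ct
from cleaveti import forcefield as ffmod
from cleaveti.crystal import Crystal, build_supercell, rock_salt_cell
from cleaveti.forcefield import (
    ForceField, lj_pair_energy, stitch_coefficients, wolf_energy,
    wolf_self_energy,
)
from cleaveti.units import REAL, REDUCED


def lj(r, eps=1.0, sig=1.0):
    return 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)


class TestStitchCoefficients:
    def test_reference_solution(self):
        # independently derived by solving the 3x3 matching system at r_m=0.5:
        # u=16128, u'=-390144, u''=10180608 -> p2=u''/2, p1=u'-2*p2*r_m, ...
        p0, p1, p2 = stitch_coefficients(1.0, 1.0, 0.5)
        assert (p0, p1, p2) == pytest.approx((1483776.0, -5480448.0, 5090304.0))

    @given(eps=st.floats(0.1, 10), sig=st.floats(0.5, 5),
           frac=st.floats(0.2, 0.9))
    @settings(max_examples=40, derandomize=True)
    def test_c2_matching_conditions(self, eps, sig, frac):
        r_m = frac * sig
        p0, p1, p2 = stitch_coefficients(eps, sig, r_m)
        h = 1e-5 * sig

        def p(r):
            return p0 + p1 * r + p2 * r * r

        assert p(r_m) == pytest.approx(lj(r_m, eps, sig), rel=1e-9)
        d_lj = (lj(r_m + h, eps, sig) - lj(r_m - h, eps, sig)) / (2 * h)
        d_p = p1 + 2 * p2 * r_m
        assert d_p == pytest.approx(d_lj, rel=1e-6)
        d2_lj = (lj(r_m + h, eps, sig) - 2 * lj(r_m, eps, sig)
                 + lj(r_m - h, eps, sig)) / h ** 2
        assert 2 * p2 == pytest.approx(d2_lj, rel=1e-4)

    def test_linear_in_epsilon(self):
        base = np.array(stitch_coefficients(1.0, 1.3, 0.65))
        scaled = np.array(stitch_coefficients(3.7, 1.3, 0.65))
        np.testing.assert_allclose(scaled, 3.7 * base, rtol=1e-12)

    def test_invalid_r_m(self):
        with pytest.raises(ValueError):
            stitch_coefficients(1.0, 1.0, 1.5)


class TestLJPairEnergy:
    def test_zero_crossing_and_minimum(self):
        assert lj_pair_energy(1.0, 1.0, 1.0, 0.5, 3.0) == pytest.approx(0.0, abs=1e-14)
        assert lj_pair_energy(2 ** (1 / 6), 1.0, 1.0, 0.5, 3.0) == pytest.approx(-1.0)

    def test_zero_beyond_cutoff(self):
        assert lj_pair_energy(3.0, 1.0, 1.0, 0.5, 3.0) == 0.0
        assert lj_pair_energy(5.0, 1.0, 1.0, 0.5, 3.0) == 0.0

    def test_core_region_is_the_stitch_polynomial(self):
        p0, p1, p2 = stitch_coefficients(1.0, 1.0, 0.5)
        r = 0.4
        expected = p0 + p1 * r + p2 * r * r
        val = lj_pair_energy(r, 1.0, 1.0, 0.5, 3.0)
        assert val == pytest.approx(expected, rel=1e-12)
        assert np.isfinite(val)
        assert val < lj(r)  # softer than the unmodified core

    def test_c2_continuity_across_r_m(self):
        """Central-difference first/second derivatives straddling the stitch
        point agree with the analytic LJ derivatives to 1e-6 relative."""
        r_m = 0.5
        h = 1e-4
        f = lambda r: lj_pair_energy(r, 1.0, 1.0, r_m, 3.0)
        dlj = 4 * (-12 * r_m ** -13 + 6 * r_m ** -7)
        d2lj = 4 * (156 * r_m ** -14 - 42 * r_m ** -8)
        d1_num = (f(r_m + h) - f(r_m - h)) / (2 * h)
        assert d1_num == pytest.approx(dlj, rel=1e-6)
        # the quadratic core has no cubic term, so the plain central stencil
        # carries an O(h) error from the u''' jump; one Richardson step
        # cancels it and isolates the (continuous) second derivative
        def d2(hh):
            return (f(r_m + hh) - 2 * f(r_m) + f(r_m - hh)) / hh ** 2
        d2_num = 2 * d2(h / 2) - d2(h)
        assert d2_num == pytest.approx(d2lj, rel=1e-6)
        # and the coefficient solve matches analytically
        p0, p1, p2 = stitch_coefficients(1.0, 1.0, r_m)
        assert p1 + 2 * p2 * r_m == pytest.approx(dlj, rel=1e-10)
        assert 2 * p2 == pytest.approx(d2lj, rel=1e-10)


class TestMixing:
    def test_geometric_rule(self):
        ff = ForceField(lj={0: (0.5, 3.0), 1: (2.0, 4.0)})
        eps, sig = ff.mixed_lj(0, 1)
        assert eps == pytest.approx(np.sqrt(0.5 * 2.0))
        assert sig == pytest.approx(np.sqrt(3.0 * 4.0))


class TestWolf:
    def test_pair_term_vanishes_at_cutoff(self):
        rc, alpha = 7.0, 0.2
        box = np.array([20.0, 20.0, 20.0])
        crystal = Crystal(box=box,
                          positions=np.array([[5.0, 5.0, 5.0],
                                              [5.0, 5.0, 5.0 + rc * (1 - 1e-12)]]),
                          types=[0, 0], charges=[1.0, -1.0],
                          masses=[1, 1], molecule=[0, 1])
        e_pair = wolf_energy(crystal, crystal.charges, alpha, rc,
                             include_self=False)
        assert e_pair == pytest.approx(0.0, abs=1e-10)

    def test_isolated_charge_gives_self_term_only(self):
        rc, alpha, q = 6.0, 0.25, 0.7
        box = np.array([30.0, 30.0, 30.0])
        crystal = Crystal(box=box, positions=np.array([[1.0, 2.0, 3.0]]),
                          types=[0], charges=[q], masses=[1], molecule=[0])
        expected = -REAL.coulomb * (erfc(alpha * rc) / (2 * rc)
                                    + alpha / np.sqrt(np.pi)) * q ** 2
        assert wolf_energy(crystal, crystal.charges, alpha, rc) \
            == pytest.approx(expected, rel=1e-12)

    def test_rock_salt_against_direct_minimum_image_sum(self):
        """Wolf energy matches a brute-force minimum-image Coulomb sum
        (and the Madelung limit) within 1% per ion on a rock-salt lattice."""
        crystal = build_supercell(rock_salt_cell(2.8, 1.0), 3, 3, 3)
        alpha, rc = 0.25, 0.49 * float(crystal.box.min())
        e_wolf = wolf_energy(crystal, crystal.charges, alpha, rc)
        i, j = np.triu_indices(crystal.n_sites, k=1)
        d = crystal.positions[j] - crystal.positions[i]
        d -= crystal.box * np.rint(d / crystal.box)
        r = np.linalg.norm(d, axis=1)
        e_direct = REAL.coulomb * np.sum(
            crystal.charges[i] * crystal.charges[j] / r)
        per_ion_dev = abs(e_wolf - e_direct) / crystal.n_sites
        assert per_ion_dev < 0.01 * abs(e_direct) / crystal.n_sites

    def test_translation_invariance(self, rng):
        crystal = build_supercell(rock_salt_cell(2.8, 0.5), 2, 2, 2)
        alpha, rc = 0.2, 0.45 * float(crystal.box.min())
        e0 = wolf_energy(crystal, crystal.charges, alpha, rc)
        shifted = crystal.copy()
        shifted.positions = np.mod(
            shifted.positions + rng.uniform(-5, 5, 3), shifted.box)
        e1 = wolf_energy(shifted, shifted.charges, alpha, rc)
        assert e1 == pytest.approx(e0, rel=1e-10)

    def test_cutoff_too_large_rejected(self):
        crystal = build_supercell(rock_salt_cell(2.8, 0.5), 2, 2, 2)
        with pytest.raises(ValueError, match="half"):
            wolf_energy(crystal, crystal.charges, 0.2, crystal.box.min())


class TestBonded:
    @pytest.fixture()
    def molecule(self):
        """One 4-site chain, isolated in a large box."""
        pos = np.array([[5.0, 5.0, 5.0], [6.5, 5.0, 5.0],
                        [6.5, 6.5, 5.0], [6.5, 6.5, 6.5]])
        crystal = Crystal(box=np.array([20.0, 20.0, 20.0]), positions=pos,
                          types=[0] * 4, charges=[0] * 4, masses=[1] * 4,
                          molecule=[0] * 4,
                          bonds=np.array([[0, 0, 1], [0, 1, 2], [0, 2, 3]]),
                          angles=np.array([[0, 0, 1, 2], [0, 1, 2, 3]]),
                          dihedrals=np.array([[0, 0, 1, 2, 3]]))
        ff = ForceField(lj={0: (0.0, 3.0)}, lj_cutoff=8.0,
                        bond_coeffs={0: (100.0, 1.5)},
                        angle_coeffs={0: (40.0, np.pi / 2)},
                        dihedral_coeffs={0: (3.0, 1, 0.0)})
        return crystal, ff

    def test_ground_state_bond_and_angle_energy_is_zero(self, molecule):
        crystal, ff = molecule
        _, breakdown = ffmod.bonded_energy(crystal, ff)
        assert breakdown["bond"] == pytest.approx(0.0, abs=1e-12)
        assert breakdown["angle"] == pytest.approx(0.0, abs=1e-12)
        # this right-angled geometry has phi = 90°: k(1 + cos phi) = k
        assert breakdown["dihedral"] == pytest.approx(3.0)

    def test_stretched_bond_quadratic(self, molecule):
        crystal, ff = molecule
        pos = crystal.positions.copy()
        pos[3, 2] += 0.3  # stretches only the terminal bond, along its axis
        _, brk = ffmod.bonded_energy(crystal, ff, pos)
        assert brk["bond"] == pytest.approx(0.5 * 100.0 * 0.3 ** 2)

    def test_against_bruteforce_sum(self, molecule, rng):
        """Vectorised bonded energy equals a naive per-term Python loop."""
        crystal, ff = molecule
        pos = crystal.positions + 0.2 * rng.standard_normal((4, 3))
        total, brk = ffmod.bonded_energy(crystal, ff, pos)

        e_bond = sum(0.5 * 100.0 * (np.linalg.norm(pos[j] - pos[i]) - 1.5) ** 2
                     for _, i, j in crystal.bonds)
        e_angle = 0.0
        for _, i, j, k in crystal.angles:
            u, v = pos[i] - pos[j], pos[k] - pos[j]
            th = np.arccos(u @ v / np.linalg.norm(u) / np.linalg.norm(v))
            e_angle += 0.5 * 40.0 * (th - np.pi / 2) ** 2
        b1, b2, b3 = pos[1] - pos[0], pos[2] - pos[1], pos[3] - pos[2]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        phi = np.arctan2(np.cross(n1, n2) @ b2 / np.linalg.norm(b2), n1 @ n2)
        e_dih = 3.0 * (1 + np.cos(phi))

        assert brk["bond"] == pytest.approx(e_bond, rel=1e-12)
        assert brk["angle"] == pytest.approx(e_angle, rel=1e-12)
        assert brk["dihedral"] == pytest.approx(e_dih, rel=1e-12)
        assert total == pytest.approx(e_bond + e_angle + e_dih, rel=1e-12)

    def test_coincident_angle_sites_rejected(self, molecule):
        crystal, ff = molecule
        pos = crystal.positions.copy()
        pos[0] = pos[1]
        with pytest.raises(ValueError, match="coincident"):
            ffmod.bonded_energy(crystal, ff, pos)


class TestForcesAreExactGradients:
    """Central-difference check of every term at 1e-6 relative tolerance."""

    @staticmethod
    def fd_check(crystal, ff, positions, n_sites=6, seed=0, h=1e-6):
        table = ffmod.build_pair_table(crystal, ff)
        _, forces = ffmod.total_energy_forces(positions, crystal, ff, table)
        rng = np.random.default_rng(seed)
        fscale = max(1.0, np.abs(forces).max())
        worst = 0.0
        for k in rng.choice(crystal.n_sites, min(n_sites, crystal.n_sites),
                            replace=False):
            for ax in range(3):
                pp, pm = positions.copy(), positions.copy()
                pp[k, ax] += h
                pm[k, ax] -= h
                up, _ = ffmod.total_energy_forces(pp, crystal, ff, table)
                um, _ = ffmod.total_energy_forces(pm, crystal, ff, table)
                worst = max(worst, abs(-(up - um) / (2 * h) - forces[k, ax]) / fscale)
        return worst

    def test_lj_crystal(self, lj_fcc, rng):
        crystal, ff = lj_fcc
        pos = crystal.positions + 0.03 * rng.standard_normal(crystal.positions.shape)
        assert self.fd_check(crystal, ff, pos) < 1e-6

    @pytest.mark.parametrize("variant", ["energy_shifted", "force_shifted"])
    def test_charged_molecular_crystal(self, diatomic, rng, variant):
        crystal, ff = diatomic
        ff = ffmod.ForceField(**{**ff.__dict__})
        ff.wolf_variant = variant
        pos = crystal.positions + 0.05 * rng.standard_normal(crystal.positions.shape)
        assert self.fd_check(crystal, ff, pos) < 1e-6

    def test_chain_crystal_with_all_bonded_terms(self, chain, rng):
        crystal, ff = chain
        pos = crystal.positions + 0.05 * rng.standard_normal(crystal.positions.shape)
        assert self.fd_check(crystal, ff, pos) < 1e-6


class TestExclusions:
    def test_12_and_13_excluded_14_included(self):
        # linear 4-site molecule: pairs (0,3) are 1-4, (0,2)/(1,3) are 1-3
        crystal = Crystal(box=np.array([20.0, 20.0, 20.0]),
                          positions=np.array([[1.0, 1, 1], [2.5, 1, 1],
                                              [4.0, 1, 1], [5.5, 1, 1]]),
                          types=[0] * 4, charges=[0.0] * 4, masses=[1] * 4,
                          molecule=[0] * 4,
                          bonds=np.array([[0, 0, 1], [0, 1, 2], [0, 2, 3]]))
        ff = ForceField(lj={0: (1.0, 3.0)}, lj_cutoff=8.0,
                        bond_coeffs={0: (10.0, 1.5)})
        table = ffmod.build_pair_table(crystal, ff)
        pairs = set(zip(table.i.tolist(), table.j.tolist()))
        assert (0, 1) not in pairs and (1, 2) not in pairs  # 1-2
        assert (0, 2) not in pairs and (1, 3) not in pairs  # 1-3
        assert (0, 3) in pairs                               # 1-4 kept

    def test_wolf_self_energy_zero_without_charges(self):
        assert wolf_self_energy(np.zeros(5), 0.2, 10.0, REAL.coulomb) == 0.0
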