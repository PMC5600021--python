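"""The four energy components: closed-form, quadrature and brute-force oracles."""

import numpy as np
import pytest
import scipy.linalg

from cepair.constants import ANGSTROM_TO_BOHR, COULOMB_KJMOL_ANGSTROM, HARTREE_TO_KJMOL
from cepair.crystal_io import Molecule
from cepair.electronic_structure import (
    CE_HF,
    PointCharges,
    compute_wavefunction,
    dimer_integral_context,
)
from cepair.energy_terms import (
    CE_B3LYP_MODEL,
    CE_HF_MODEL,
    DispersionParams,
    PairEnergy,
    PolarizabilityTable,
    e_dispersion,
    e_electrostatic,
    e_exchange_repulsion,
    e_polarization,
    e_total,
    pair_energy,
)
from cepair.fixtures import make_dimer


def ion(element, position, charge, polarizable=False):
    mol = Molecule(
        [(element, np.asarray(position, dtype=float))],
        net_charge=charge,
        is_monatomic_ion=True,
    )
    return PointCharges(mol, polarizable=polarizable)


class TestPackagedConstants:
    def test_scale_factor_sets(self):
        assert tuple(CE_B3LYP_MODEL.scale_factors) == (1.057, 0.740, 0.871, 0.618)
        assert tuple(CE_HF_MODEL.scale_factors) == (1.019, 0.651, 0.901, 0.811)

    def test_ion_polarizabilities(self):
        t = PolarizabilityTable()
        assert t.get("Li", "cation") == 0.190
        assert t.get("Na", "cation") == 0.986
        assert t.get("Ca", "cation") == 3.2
        assert t.get("F", "anion") == 7.25
        assert t.get("Cl", "anion") == 21.2
        assert t.get("Br", "anion") == 27.9
        assert t.get("I", "anion") == 39.6
        assert t.get("Li", "neutral") == 164.0
        assert t.get("F", "neutral") == 3.70

    def test_cation_much_smaller_than_atom(self):
        t = PolarizabilityTable()
        for el in ("Li", "Na", "K", "Mg", "Ca"):
            assert t.get(el, "cation") < 0.1 * t.get(el, "neutral")

    def test_missing_entry_names_element_and_class(self):
        with pytest.raises(KeyError, match="H.*cation"):
            PolarizabilityTable().get("H", "cation")


class TestElectrostatic:
    def test_unit_charges_at_8p175(self):
        a = ion("H", (0, 0, 0), +1)
        b = ion("H", (0, 0, 8.175), +1)
        e = e_electrostatic(a, b)
        assert e == pytest.approx(COULOMB_KJMOL_ANGSTROM / 8.175, abs=1e-9)
        assert e == pytest.approx(169.95, abs=0.01)

    def test_neutral_monomers_far_apart(self):
        a, b = make_dimer("He", 200.0)
        wa, wb = compute_wavefunction(a, CE_HF), compute_wavefunction(b, CE_HF)
        assert abs(e_electrostatic(wa, wb)) < 0.001

    def test_symmetric_under_swap(self, he_dimer_25):
        wa, wb = he_dimer_25
        assert e_electrostatic(wa, wb) == pytest.approx(e_electrostatic(wb, wa), abs=1e-9)

    def test_h_atom_densities_at_10A_vs_quadrature(self):
        """Full classical interaction of two neutral H atoms at 10 Å against
        an independent radial-quadrature evaluation (nuclei + clouds)."""
        a, b = make_dimer("H_atom", 10.0)
        wa, wb = compute_wavefunction(a, CE_HF), compute_wavefunction(b, CE_HF)
        e = e_electrostatic(wa, wb)

        # oracle: spherical-density potential of A evaluated radially
        def radial_density(wfn, r):
            shells = wfn.scf.basis.shells
            norms = wfn.scf.engine._norms
            out = []
            for rr in np.atleast_1d(r):
                phi = np.array(
                    [
                        n
                        * sum(
                            c * np.exp(-z * rr * rr)
                            for z, c in zip(s.exponents, s.coefficients)
                        )
                        for s, n in zip(shells, norms)
                    ]
                )
                out.append(phi @ wfn.density @ phi)
            return np.array(out)

        r = np.linspace(1e-6, 40.0, 8000)
        dr = r[1] - r[0]
        rho = radial_density(wa, r)
        q_in = np.cumsum(4 * np.pi * rho * r**2) * dr
        outer = np.cumsum((4 * np.pi * rho * r)[::-1])[::-1] * dr
        v_cloud = q_in / r + outer  # potential of A's electron cloud at radius r

        R = 10.0 * ANGSTROM_TO_BOHR
        # nucleus-nucleus + nucleus(B)-cloud(A) + nucleus(A)-cloud(B)
        vn = 1.0 / R - np.interp(R, r, v_cloud) * 2.0
        # cloud-cloud by quadrature over B's density
        from numpy.polynomial.legendre import leggauss

        xs, ws = leggauss(400)
        s = 0.5 * (xs + 1) * 15.0
        sw = ws * 0.5 * 15.0
        mu, mw = leggauss(400)
        ee = 0.0
        for si, swi in zip(s, sw):
            rho_b = radial_density(wb, si)[0]
            dist = np.sqrt(R * R + si * si - 2 * R * si * mu)
            v_here = np.where(dist <= r[-1], np.interp(dist, r, v_cloud), q_in[-1] / dist)
            ee += swi * rho_b * si * si * np.sum(mw * v_here) * 2 * np.pi
        oracle = (vn + ee) * HARTREE_TO_KJMOL
        assert e == pytest.approx(oracle, abs=0.01)

    def test_ion_pair_long_range_coulomb(self):
        """Wavefunction ions behave as point charges beyond 8 Å within 1%."""
        li = Molecule([("Li", (0.0, 0.0, 0.0))], net_charge=1)
        f = Molecule([("F", (0.0, 0.0, 10.0))], net_charge=-1)
        wa = compute_wavefunction(li, CE_HF)
        wb = compute_wavefunction(f, CE_HF)
        e = e_electrostatic(wa, wb)
        assert e == pytest.approx(-COULOMB_KJMOL_ANGSTROM / 10.0, rel=0.01)

    def test_coincident_nuclei_rejected(self):
        a = ion("H", (0, 0, 0), +1)
        b = ion("H", (0, 0, 0), +1)
        with pytest.raises(ValueError, match="singular"):
            e_electrostatic(a, b)


class TestPolarization:
    def test_closed_form_li_cation(self):
        """Li+ (alpha = 0.190 au) 5 Å from a unit charge: -(1/2) alpha F^2."""
        li = ion("Li", (0, 0, 0), +1, polarizable=True)
        probe = ion("H", (0, 0, 5.0), +1)
        F = 1.0 / (5.0 * ANGSTROM_TO_BOHR) ** 2
        expected = -0.5 * 0.190 * F * F * HARTREE_TO_KJMOL
        assert e_polarization(li, probe) == pytest.approx(expected, rel=1e-12)
        assert e_polarization(li, probe) == pytest.approx(-0.031, abs=0.001)

    def test_neutral_atom_ratio(self):
        """Neutral Li (alpha 164.0) vs Li+ (0.190): |E_pol| ratio is exact."""
        li_ion = ion("Li", (0, 0, 0), +1, polarizable=True)
        li_neutral = PointCharges(
            Molecule([("Li", (0.0, 0.0, 0.0))], net_charge=1), polarizable=True
        )
        li_neutral.molecule.is_monatomic_ion = False  # force neutral-atom alpha
        probe = ion("H", (0, 0, 5.0), +1)
        ratio = e_polarization(li_neutral, probe) / e_polarization(li_ion, probe)
        assert ratio == pytest.approx(164.0 / 0.190, rel=1e-12)

    def test_ion_override_reduces_magnitude(self):
        li_ion = ion("Li", (0, 0, 0), +1, polarizable=True)
        li_neutral = PointCharges(
            Molecule([("Li", (0.0, 0.0, 0.0))], net_charge=1), polarizable=True
        )
        li_neutral.molecule.is_monatomic_ion = False
        probe = ion("H", (0, 0, 5.0), +1)
        assert abs(e_polarization(li_ion, probe)) < abs(e_polarization(li_neutral, probe))

    def test_zero_field_gives_zero(self):
        a, b = make_dimer("He", 500.0)
        wa, wb = compute_wavefunction(a, CE_HF), compute_wavefunction(b, CE_HF)
        assert e_polarization(wa, wb) == pytest.approx(0.0, abs=1e-6)

    def test_always_nonpositive(self, he_dimer_25):
        wa, wb = he_dimer_25
        assert e_polarization(wa, wb) <= 0.0


class TestDispersion:
    def test_two_carbons_closed_form(self):
        p = DispersionParams()
        a = Molecule([("C", (0.0, 0.0, 0.0))])
        b = Molecule([("C", (0.0, 0.0, 4.0))])
        rr = 2 * p.r_vdw("C")
        fdmp = 1.0 / (1.0 + np.exp(-p.d * (4.0 / rr - 1.0)))
        expected = -p.s6 * fdmp * p.c6("C") / 0.4**6 / 1000.0
        assert e_dispersion(a, b, p) == pytest.approx(expected, abs=1e-10)

    def test_far_limit(self):
        a = Molecule([("C", (0.0, 0.0, 0.0))])
        b = Molecule([("C", (0.0, 0.0, 1000.0))])
        assert abs(e_dispersion(a, b)) < 1e-10

    def test_swap_symmetric_exactly(self, water_molecule):
        other = water_molecule.translated(np.array([0.0, 1.0, 4.0]))
        assert e_dispersion(water_molecule, other) == e_dispersion(other, water_molecule)

    def test_always_nonpositive_and_combination_rule(self):
        p = DispersionParams()
        a = Molecule([("C", (0.0, 0.0, 0.0))])
        b = Molecule([("N", (0.0, 0.0, 3.0))])
        assert e_dispersion(a, b, p) < 0
        # C6 combination is the geometric mean
        e_cn = e_dispersion(a, b, p)
        rr_cn = p.r_vdw("C") + p.r_vdw("N")
        fdmp = 1.0 / (1.0 + np.exp(-p.d * (3.0 / rr_cn - 1.0)))
        assert e_cn == pytest.approx(
            -fdmp * np.sqrt(p.c6("C") * p.c6("N")) / 0.3**6 / 1000.0, abs=1e-10
        )

    def test_missing_element_raises(self):
        a = Molecule([("Cs", (0.0, 0.0, 0.0))])
        b = Molecule([("C", (0.0, 0.0, 3.0))])
        with pytest.raises(KeyError, match="Cs"):
            e_dispersion(a, b)


def brute_force_antisymmetrised_energy(wa, wb, ctx, spins_a=None, spins_b=None):
    """Independent construction: QR-orthonormalise the pooled occupied
    orbitals (any orthonormalisation of the same span gives the same
    determinant energy) and evaluate the energy with explicit loops."""
    S = ctx.overlap
    h = ctx.kinetic + ctx.nuclear_attraction
    eri = ctx.eri
    L = np.linalg.cholesky(S)

    def density(occs):
        if not occs:
            return np.zeros_like(S)
        C = np.column_stack(occs)
        # orthonormalise w.r.t. metric S via QR in the Cholesky frame
        Q, _ = np.linalg.qr(L.T @ C)
        C_orth = np.linalg.solve(L.T, Q)
        return C_orth @ C_orth.T

    na, nb = ctx.na, ctx.nb

    def embed(C, block):
        out = np.zeros((na + nb, C.shape[1]))
        out[block] = C
        return out

    occ_alpha = [embed(wa.occupied_alpha, ctx.slice_a), embed(wb.occupied_alpha, ctx.slice_b)]
    occ_beta = [embed(wa.occupied_beta, ctx.slice_a), embed(wb.occupied_beta, ctx.slice_b)]
    Pa = density([c[:, k] for c in occ_alpha for k in range(c.shape[1])])
    Pb = density([c[:, k] for c in occ_beta for k in range(c.shape[1])])
    P = Pa + Pb
    n = len(S)
    e1 = np.sum(P * h)
    e2 = 0.0
    for p in range(n):
        for q in range(n):
            for r in range(n):
                for s in range(n):
                    e2 += 0.5 * P[p, q] * P[r, s] * eri[p, q, r, s]
                    e2 -= 0.5 * (Pa[p, q] * Pa[r, s] + Pb[p, q] * Pb[r, s]) * eri[p, r, q, s]
    return e1 + e2 + ctx.nuclear_repulsion_total


class TestExchangeRepulsion:
    def test_vanishes_at_separation(self):
        a, b = make_dimer("He", 100.0)
        wa, wb = compute_wavefunction(a, CE_HF), compute_wavefunction(b, CE_HF)
        assert abs(e_exchange_repulsion(wa, wb)) < 0.001

    def test_he_he_brute_force_oracle(self, he_dimer_25):
        """He–He at 2.5 Å against the independent antisymmetrised-product
        construction (QR orthonormalisation + explicit-loop energy)."""
        wa, wb = he_dimer_25
        ctx = dimer_integral_context(wa, wb)
        e_model = e_exchange_repulsion(wa, wb, context=ctx)
        assert e_model > 0
        e_dimer = brute_force_antisymmetrised_energy(wa, wb, ctx)

        def monomer_hf(w):
            from cepair.qm.scf import hf_energy_expression, nuclear_repulsion

            return hf_energy_expression(
                w.scf.hcore,
                w.scf.engine.eri(),
                w.scf.density_alpha,
                w.scf.density_beta,
                nuclear_repulsion(w.nuclear_charges, w.nuclear_coords_bohr),
            )

        e_ele = e_electrostatic(wa, wb, context=ctx) / HARTREE_TO_KJMOL
        oracle = (e_dimer - monomer_hf(wa) - monomer_hf(wb) - e_ele) * HARTREE_TO_KJMOL
        assert e_model == pytest.approx(oracle, abs=0.01)

    def test_two_doublets_couple_high_spin(self, h_radical_dimer):
        """Two doublet H atoms: the pooled determinant must be the triplet
        (both unpaired electrons alpha), matching an explicitly
        triplet-coupled oracle."""
        wa, wb = h_radical_dimer
        assert wa.scf.n_alpha == 1 and wa.scf.n_beta == 0
        ctx = dimer_integral_context(wa, wb)
        e_model = e_exchange_repulsion(wa, wb, context=ctx)

        # explicit triplet coupling: both occupied spin orbitals in the
        # alpha block, none in beta
        e_dimer = brute_force_antisymmetrised_energy(wa, wb, ctx)
        from cepair.qm.scf import hf_energy_expression, nuclear_repulsion

        def monomer_hf(w):
            return hf_energy_expression(
                w.scf.hcore,
                w.scf.engine.eri(),
                w.scf.density_alpha,
                w.scf.density_beta,
                nuclear_repulsion(w.nuclear_charges, w.nuclear_coords_bohr),
            )

        e_ele = e_electrostatic(wa, wb, context=ctx) / HARTREE_TO_KJMOL
        oracle = (e_dimer - monomer_hf(wa) - monomer_hf(wb) - e_ele) * HARTREE_TO_KJMOL
        assert e_model == pytest.approx(oracle, abs=0.01)
        # triplet H2 at 2.5 Å is repulsive
        assert e_model > 0

    def test_overlapping_monomers_rejected(self):
        # two identical monomers on the same site: pooled occupied set is
        # exactly linearly dependent
        wa = compute_wavefunction(Molecule([("He", (0.0, 0.0, 0.0))]), CE_HF)
        wb = compute_wavefunction(Molecule([("He", (0.0, 0.0, 0.0))]), CE_HF)
        with pytest.raises(ValueError, match="linear"):
            e_exchange_repulsion(wa, wb)


class TestTotals:
    def test_zero_components(self):
        pe = e_total(PairEnergy(0.0, 0.0, 0.0, 0.0), CE_B3LYP_MODEL)
        assert pe.e_tot == 0.0

    def test_unit_components_both_models(self):
        pe = e_total(PairEnergy(1.0, 1.0, 1.0, 1.0), CE_B3LYP_MODEL)
        assert pe.e_tot == pytest.approx(3.286, abs=1e-12)
        pe = e_total(PairEnergy(1.0, 1.0, 1.0, 1.0), CE_HF_MODEL)
        assert pe.e_tot == pytest.approx(3.382, abs=1e-12)

    def test_scaled_components_sum_to_total(self):
        pe = e_total(PairEnergy(-10.0, -2.0, -7.5, 12.0), CE_B3LYP_MODEL)
        assert pe.scaled_components(CE_B3LYP_MODEL).sum() == pytest.approx(pe.e_tot)

    def test_display_rounds_to_whole_kjmol(self):
        pe = e_total(PairEnergy(-10.0, -2.0, -7.5, 12.0), CE_B3LYP_MODEL)
        assert pe.e_tot_display == round(pe.e_tot)


class TestRigidBodyInvariance:
    def test_all_terms_invariant_under_rigid_motion(self):
        """Rotating + translating the H2–H2 dimer as a whole changes no
        component by more than 0.01 kJ/mol."""
        a, b = make_dimer("H2", 3.0, orientation=(0.0, 90.0, 0.0))
        rot = scipy.linalg.expm(
            np.array([[0.0, -0.3, 0.1], [0.3, 0.0, -0.2], [-0.1, 0.2, 0.0]])
        )
        shift = np.array([1.0, -2.0, 0.7])

        def moved(mol):
            return Molecule(
                [(el, rot @ pos + shift) for el, pos in mol.atoms],
                net_charge=mol.net_charge,
                multiplicity=mol.multiplicity,
            )

        pe1 = pair_energy(
            compute_wavefunction(a, CE_HF), compute_wavefunction(b, CE_HF), CE_HF_MODEL
        )
        pe2 = pair_energy(
            compute_wavefunction(moved(a), CE_HF),
            compute_wavefunction(moved(b), CE_HF),
            CE_HF_MODEL,
        )
        assert np.allclose(pe1.components(), pe2.components(), atol=0.01)

    def test_all_terms_swap_symmetric(self):
        a, b = make_dimer("H2", 3.0, orientation=(0.0, 90.0, 0.0))
        wa, wb = compute_wavefunction(a, CE_HF), compute_wavefunction(b, CE_HF)
        pe_ab = pair_energy(wa, wb, CE_HF_MODEL)
        pe_ba = pair_energy(wb, wa, CE_HF_MODEL)
        assert np.allclose(pe_ab.components(), pe_ba.components(), atol=1e-6)
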