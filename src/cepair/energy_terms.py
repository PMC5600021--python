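"""The four components of the pairwise model interaction energy.

For a molecule/ion pair (A, B) the model energy is

    E_tot = k_ele * E_ele + k_pol * E_pol + k_dis * E_dis + k_rep * E_rep

with

* ``E_ele`` — classical Coulomb energy between the two unperturbed monomer
  charge distributions (nuclei + SCF electron densities);
* ``E_pol`` — sum over atoms of -(1/2) alpha |F|^2, where F is the electric
  field of the partner's total charge distribution at each nucleus and alpha
  an isotropic atomic polarizability (monatomic-ion values where the species
  is a bare ion);
* ``E_dis`` — Grimme D2 pairwise dispersion summed over intermolecular atom
  pairs;
* ``E_rep`` — exchange–repulsion from the normalised antisymmetrised product
  of the two monomers' occupied spin orbitals evaluated with the dimer
  Hamiltonian (Löwdin orthonormalisation of the pooled occupied set followed
  by a Hartree–Fock-like energy evaluation), relative to the monomers and
  the classical electrostatic energy.

The scale factors are calibrated against counterpoise-corrected B3LYP-D2
reference energies; the packaged values are the published CE-HF and
CE-B3LYP sets.  Components are stored unscaled in kJ mol^-1; scaled
components are available for display.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import scipy.linalg

from .constants import HARTREE_TO_KJMOL, normalize_symbol
from .crystal_io import Molecule
from .electronic_structure import (
    CE_B3LYP,
    CE_HF,
    DimerIntegralContext,
    PointCharges,
    TheorySpec,
    Wavefunction,
    dimer_integral_context,
    field_and_potential_at_points,
)
from .qm.scf import hf_energy_expression

__all__ = [
    "EnergyModel",
    "CE_HF_MODEL",
    "CE_B3LYP_MODEL",
    "PolarizabilityTable",
    "DispersionParams",
    "PairEnergy",
    "FieldSample",
    "e_electrostatic",
    "e_polarization",
    "e_dispersion",
    "e_exchange_repulsion",
    "e_total",
    "pair_energy",
]


@dataclass(frozen=True)
class EnergyModel:
    """Model id, the four dimensionless scale factors and the theory level."""

    model_id: str
    k_ele: float
    k_pol: float
    k_dis: float
    k_rep: float
    theory: TheorySpec

    @property
    def scale_factors(self) -> np.ndarray:
        return np.array([self.k_ele, self.k_pol, self.k_dis, self.k_rep])


#: Published scale factors fitted to counterpoise-corrected B3LYP-D2
#: benchmark energies over 1794 (CE-B3LYP) / 1725 (CE-HF) molecule/ion pairs.
CE_HF_MODEL = EnergyModel("CE-HF", 1.019, 0.651, 0.901, 0.811, CE_HF)
CE_B3LYP_MODEL = EnergyModel("CE-B3LYP", 1.057, 0.740, 0.871, 0.618, CE_B3LYP)


class PolarizabilityTable:
    """Isotropic atomic polarizabilities (au) by element and species class.

    Species classes: ``neutral``, ``cation`` and ``anion``; the ion values
    apply only to monatomic, non-covalently-bound ions.
    """

    def __init__(self, data: dict | None = None):
        if data is None:
            text = resources.files("cepair.data").joinpath("polarizabilities.json").read_text()
            data = json.loads(text)
        self._data = data

    def get(self, element: str, species_class: str = "neutral") -> float:
        element = normalize_symbol(element)
        table = self._data.get(species_class)
        if table is None or element not in table:
            raise KeyError(
                f"no isotropic polarizability for element {element} "
                f"(species class {species_class!r})"
            )
        return float(table[element])

    def for_molecule(self, mol: Molecule) -> np.ndarray:
        """Per-atom polarizabilities honouring the monatomic-ion override."""
        if mol.is_monatomic_ion:
            cls = "cation" if mol.net_charge > 0 else "anion"
            return np.array([self.get(mol.elements[0], cls)])
        return np.array([self.get(el, "neutral") for el in mol.elements])


class DispersionParams:
    """Grimme D2 constants: C6 (J nm^6 mol^-1), vdW radii (Å), damping d, s6."""

    def __init__(self, data: dict | None = None):
        if data is None:
            text = resources.files("cepair.data").joinpath("d2_params.json").read_text()
            data = json.loads(text)
        self.s6 = float(data["s6"])
        self.d = float(data["d"])
        self._c6 = data["c6"]
        self._r = data["r_vdw"]

    def c6(self, element: str) -> float:
        element = normalize_symbol(element)
        if element not in self._c6:
            raise KeyError(f"no D2 C6 coefficient for element {element}")
        return float(self._c6[element])

    def r_vdw(self, element: str) -> float:
        element = normalize_symbol(element)
        if element not in self._r:
            raise KeyError(f"no D2 van der Waals radius for element {element}")
        return float(self._r[element])


@dataclass(frozen=True)
class FieldSample:
    """Electric field (au) of one monomer evaluated at a partner nucleus."""

    position: tuple  # Å
    field: tuple  # au
    source: str  # label of the monomer producing the field

    def __post_init__(self):
        if not np.all(np.isfinite(self.field)):
            raise ValueError("field must be finite")


@dataclass
class PairEnergy:
    """Unscaled components + scaled total for one molecule/ion pair (kJ/mol)."""

    e_ele: float
    e_pol: float
    e_dis: float
    e_rep: float
    model_id: str = ""
    e_tot: float = 0.0
    label: str = ""
    symmetry: str = ""
    centroid_distance: float = 0.0
    multiplicity_count: int = 1

    def components(self) -> np.ndarray:
        return np.array([self.e_ele, self.e_pol, self.e_dis, self.e_rep])

    def scaled_components(self, model: EnergyModel) -> np.ndarray:
        """k * E per term: these sum exactly to ``e_tot`` (display option)."""
        return self.components() * model.scale_factors

    @property
    def e_tot_display(self) -> int:
        """Whole-number kJ/mol, the recommended reporting precision."""
        return int(round(self.e_tot))

    def to_record(self) -> dict:
        return {
            "label": self.label,
            "model": self.model_id,
            "symmetry": self.symmetry,
            "centroid_distance": round(self.centroid_distance, 4),
            "multiplicity": self.multiplicity_count,
            "e_ele": self.e_ele,
            "e_pol": self.e_pol,
            "e_dis": self.e_dis,
            "e_rep": self.e_rep,
            "e_tot": self.e_tot,
            "e_tot_display": self.e_tot_display,
        }


# ---------------------------------------------------------------------------
# electrostatic


def _is_point(system) -> bool:
    return isinstance(system, PointCharges)


def e_electrostatic(wfn_a, wfn_b, context: DimerIntegralContext | None = None) -> float:
    """Classical Coulomb energy between the unperturbed monomer charge
    distributions, in kJ mol^-1.  Symmetric under argument swap.

    Accepts :class:`Wavefunction` or :class:`PointCharges` monomers.
    """
    # nuclear-nuclear part (point charges are "nuclei" with their charge)
    qa, ra = wfn_a.nuclear_charges, wfn_a.nuclear_coords_bohr
    qb, rb = wfn_b.nuclear_charges, wfn_b.nuclear_coords_bohr
    d = np.linalg.norm(ra[:, None, :] - rb[None, :, :], axis=-1)
    if np.any(d < 1e-8):
        raise ValueError("coincident nuclei across monomers (singular)")
    e_nn = float(np.sum(np.outer(qa, qb) / d))

    e_ne = 0.0
    e_ee = 0.0
    a_real = not _is_point(wfn_a)
    b_real = not _is_point(wfn_b)
    if a_real and b_real:
        ctx = context or dimer_integral_context(wfn_a, wfn_b)
        Da = wfn_a.density
        Db = wfn_b.density
        Vb_on_a = ctx.nuclear_attraction_b[ctx.slice_a, ctx.slice_a]
        Va_on_b = ctx.nuclear_attraction_a[ctx.slice_b, ctx.slice_b]
        e_ne = float(np.sum(Da * Vb_on_a) + np.sum(Db * Va_on_b))
        eri_cross = ctx.eri[ctx.slice_a, ctx.slice_a, ctx.slice_b, ctx.slice_b]
        e_ee = float(np.einsum("pq,pqrs,rs->", Da, eri_cross, Db))
    elif a_real or b_real:
        wfn, probe = (wfn_a, wfn_b) if a_real else (wfn_b, wfn_a)
        V = wfn.scf.engine.point_charge_potential(
            probe.nuclear_charges, probe.nuclear_coords_bohr
        )
        e_ne = float(np.sum(wfn.density * V))
    return (e_nn + e_ne + e_ee) * HARTREE_TO_KJMOL


# ---------------------------------------------------------------------------
# polarization


def e_polarization(
    wfn_a,
    wfn_b,
    table: PolarizabilityTable | None = None,
    return_samples: bool = False,
):
    """Polarization energy -(1/2) sum_atoms alpha |F|^2 in kJ mol^-1 (<= 0).

    F is evaluated at each nucleus of A from B's total charge distribution
    and vice versa; monatomic ions use their ion polarizability.
    """
    table = table or PolarizabilityTable()
    total = 0.0
    samples = []
    for target, source in ((wfn_a, wfn_b), (wfn_b, wfn_a)):
        if _is_point(target) and not target.polarizable:
            continue
        mol = target.molecule
        alphas = table.for_molecule(mol)
        points = mol.coordinates
        results = field_and_potential_at_points(source, points)
        for (pos, alpha, (_, F)) in zip(points, alphas, results):
            total += -0.5 * alpha * float(F @ F)
            samples.append(
                FieldSample(
                    position=tuple(pos),
                    field=tuple(F),
                    source=getattr(source.molecule, "label", ""),
                )
            )
    energy = total * HARTREE_TO_KJMOL
    if return_samples:
        return energy, samples
    return energy


# ---------------------------------------------------------------------------
# dispersion


def e_dispersion(mol_a, mol_b, params: DispersionParams | None = None) -> float:
    """Grimme D2 dispersion over intermolecular atom pairs, kJ mol^-1 (<= 0).

    E = -s6 * sum_ij f_dmp(R_ij) C6_ij / R_ij^6 with
    f_dmp(R) = 1 / (1 + exp(-d (R/R_r - 1))), C6_ij = sqrt(C6_i C6_j) and
    R_r the sum of the two van der Waals radii.
    """
    params = params or DispersionParams()
    mol_a = mol_a.molecule if hasattr(mol_a, "molecule") else mol_a
    mol_b = mol_b.molecule if hasattr(mol_b, "molecule") else mol_b
    energy = 0.0  # J/mol
    for el_i, pos_i in mol_a.atoms:
        for el_j, pos_j in mol_b.atoms:
            R = float(np.linalg.norm(pos_i - pos_j))  # Å
            c6 = np.sqrt(params.c6(el_i) * params.c6(el_j))  # J nm^6 / mol
            rr = params.r_vdw(el_i) + params.r_vdw(el_j)
            fdmp = 1.0 / (1.0 + np.exp(-params.d * (R / rr - 1.0)))
            energy -= params.s6 * fdmp * c6 / (R / 10.0) ** 6  # R in nm
    return energy / 1000.0  # kJ/mol


# ---------------------------------------------------------------------------
# exchange-repulsion


def e_exchange_repulsion(
    wfn_a: Wavefunction,
    wfn_b: Wavefunction,
    context: DimerIntegralContext | None = None,
) -> float:
    """Exchange–repulsion energy from the antisymmetrised product of the
    monomer spin orbitals, in kJ mol^-1.

    The pooled occupied spin orbitals of the two monomers are Löwdin
    symmetric-orthonormalised on the dimer basis and the Hartree–Fock energy
    expression of that single determinant is evaluated with the dimer
    Hamiltonian; the two monomer energies (same expression, own orbitals)
    and the classical electrostatic energy are subtracted.  For two
    open-shell monomers the unpaired spins combine high-spin (e.g. two
    doublets couple to the UHF triplet).
    """
    ctx = context or dimer_integral_context(wfn_a, wfn_b)
    S = ctx.overlap
    h = ctx.kinetic + ctx.nuclear_attraction
    eri = ctx.eri

    def pooled_density(occ_a: np.ndarray, occ_b: np.ndarray) -> np.ndarray:
        n_occ = occ_a.shape[1] + occ_b.shape[1]
        C = np.zeros((ctx.na + ctx.nb, n_occ))
        C[ctx.slice_a, : occ_a.shape[1]] = occ_a
        C[ctx.slice_b, occ_a.shape[1] :] = occ_b
        if n_occ == 0:
            return np.zeros((ctx.na + ctx.nb, ctx.na + ctx.nb))
        M = C.T @ S @ C
        evals = np.linalg.eigvalsh(M)
        if evals.min() < 1e-10:
            raise ValueError(
                "pooled occupied orbitals are (near-)linearly dependent; "
                "check the dimer geometry for overlapping molecules"
            )
        C_orth = C @ scipy.linalg.fractional_matrix_power(M, -0.5).real
        return C_orth @ C_orth.T

    Pa = pooled_density(wfn_a.occupied_alpha, wfn_b.occupied_alpha)
    Pb = pooled_density(wfn_a.occupied_beta, wfn_b.occupied_beta)
    e_dimer = hf_energy_expression(h, eri, Pa, Pb, ctx.nuclear_repulsion_total)

    # monomer energies with the same (HF-like) expression on their own basis
    def monomer_energy(wfn: Wavefunction) -> float:
        scf = wfn.scf
        from .qm.scf import nuclear_repulsion

        e_nuc = nuclear_repulsion(wfn.nuclear_charges, wfn.nuclear_coords_bohr)
        return hf_energy_expression(
            scf.hcore,
            scf.engine.eri(),
            scf.density_alpha,
            scf.density_beta,
            e_nuc,
        )

    e_ele_hartree = e_electrostatic(wfn_a, wfn_b, context=ctx) / HARTREE_TO_KJMOL
    e_rep = e_dimer - monomer_energy(wfn_a) - monomer_energy(wfn_b) - e_ele_hartree
    return e_rep * HARTREE_TO_KJMOL


# ---------------------------------------------------------------------------
# totals


def e_total(components: PairEnergy, model: EnergyModel) -> PairEnergy:
    """Attach the scaled total to a set of components."""
    components.e_tot = float(components.components() @ model.scale_factors)
    components.model_id = model.model_id
    return components


def pair_energy(
    wfn_a,
    wfn_b,
    model: EnergyModel = CE_HF_MODEL,
    polarizabilities: PolarizabilityTable | None = None,
    dispersion: DispersionParams | None = None,
    label: str = "",
    symmetry: str = "",
) -> PairEnergy:
    """All four components + scaled total for one monomer pair."""
    both_real = not (_is_point(wfn_a) or _is_point(wfn_b))
    ctx = dimer_integral_context(wfn_a, wfn_b) if both_real else None
    pe = PairEnergy(
        e_ele=e_electrostatic(wfn_a, wfn_b, context=ctx),
        e_pol=e_polarization(wfn_a, wfn_b, table=polarizabilities),
        e_dis=e_dispersion(wfn_a, wfn_b, params=dispersion),
        e_rep=e_exchange_repulsion(wfn_a, wfn_b, context=ctx) if both_real else 0.0,
        label=label,
        symmetry=symmetry,
        centroid_distance=float(
            np.linalg.norm(wfn_a.molecule.center_of_mass - wfn_b.molecule.center_of_mass)
        ),
    )
    return e_total(pe, model)
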