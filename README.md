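# cepair

Pairwise model interaction energies and energy frameworks for molecular
crystals.

Understanding why molecules pack the way they do requires energies, not just
geometries: which contacts in a crystal stabilize the structure, which are
forced and destabilizing, and how strongly neighbouring molecules bind.
`cepair` computes an accurate yet inexpensive estimate of the interaction
energy between molecule/ion pairs extracted from a crystal structure, using
the scaled four-term decomposition

```
E_tot = k_ele·E_ele + k_pol·E_pol + k_dis·E_dis + k_rep·E_rep
```

where, for unperturbed monomer wavefunctions computed at a fixed crystal
geometry,

* **E_ele** is the classical Coulomb energy between the two monomer charge
  distributions (nuclei + SCF electron densities);
* **E_pol** is a sum over atoms of −½·α·|**F**|², with **F** the electric
  field of the partner monomer at each nucleus and α an isotropic atomic
  polarizability (with much smaller dedicated values for monatomic ions);
* **E_dis** is Grimme's D2 pairwise dispersion, −s₆·Σ f_dmp(R)·C₆/R⁶, summed
  over intermolecular atom pairs;
* **E_rep** is the exchange–repulsion energy of the normalized
  antisymmetrized product of the two monomers' occupied spin orbitals,
  evaluated with the dimer Hamiltonian.

The scale factors *k* are calibrated against counterpoise-corrected B3LYP-D2
reference energies.  Two published parameter sets are packaged:

| model    | monomer theory        | k_ele | k_pol | k_dis | k_rep |
|----------|-----------------------|-------|-------|-------|-------|
| CE-HF    | HF/3-21G              | 1.019 | 0.651 | 0.901 | 0.811 |
| CE-B3LYP | B3LYP/6-31G(d,p)–DGDZVP | 1.057 | 0.740 | 0.871 | 0.618 |

Around this core the package provides the full crystal pipeline: CIF input
with symmetry expansion, molecule/ion perception across cell boundaries,
X—H bond normalization to neutron-standard lengths, nearest-neighbour
clusters deduplicated into symmetry-unique pairs, converged lattice-energy
summation for neutral molecular crystals, "energy framework" cylinder graphs
(including destabilizing interactions), and the least-squares machinery to
(re)calibrate the scale factors against benchmark tables.

The bundled electronic-structure backend is a Gaussian-basis
restricted/unrestricted Hartree–Fock engine (so the CE-HF model runs out of
the box); DFT-capable engines for CE-B3LYP monomer wavefunctions plug in
through a small documented backend protocol
(`cepair.electronic_structure.register_backend`).

## Worked example

Interaction energy of a hydrogen-bonded hydrogen fluoride pair (a linear
H—F···H—F chain, centres of mass 3.1 Å apart) with the CE-HF model:

```python
from cepair import CE_HF, CE_HF_MODEL, compute_wavefunction, pair_energy
from cepair.fixtures import make_dimer

mol_a, mol_b = make_dimer("HF", 3.1)
wfn_a = compute_wavefunction(mol_a, CE_HF)
wfn_b = compute_wavefunction(mol_b, CE_HF)
pe = pair_energy(wfn_a, wfn_b, CE_HF_MODEL)
print(pe.e_ele, pe.e_pol, pe.e_dis, pe.e_rep, pe.e_tot_display)
```

prints (kJ mol⁻¹, unscaled components and the scaled rounded total):

```
E_ele = -19.25   E_pol = -2.34   E_dis = -1.92   E_rep = 2.28   E_tot = -21
```

The attraction is dominated by electrostatics (the hydrogen bond), with
small polarization and dispersion contributions partly cancelled by
exchange–repulsion; totals are reported as whole numbers because individual
pairwise model energies are not reliable below ~1 kJ mol⁻¹.

The same machinery runs from the shell.  Starting from any CIF (here a
generated toy crystal):

```sh
cepair fixture point_lattice -p element=He -p a=5.0 -o he.cif
cepair pairs he.cif --radius 5.1          # symmetry-unique pair table (CSV)
cepair lattice he.cif --r-max 12 --tol 0.1  # shell-by-shell lattice sum
cepair framework he.cif --component tot --cutoff 0.001 -o scene.json
cepair fit benchmark.csv                  # scale-factor calibration
```

Crystals with charged or open-shell species need a small YAML config mapping
molecule labels to formal charge/multiplicity (`--config species.yaml`);
odd-electron species default to doublets, and open-shell pairs are coupled
high-spin in the repulsion term.

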