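# Methods

This note records the model implemented by `cepair`, the numerical choices
behind it, and what the test fixtures do and do not demonstrate.

## The model

For a pair of molecules or ions (A, B) at fixed (crystal) geometry the model
interaction energy is

    E_tot = k_ele·E_ele + k_pol·E_pol + k_dis·E_dis + k_rep·E_rep

with the four components computed from *unperturbed* monomer wavefunctions —
no dimer SCF, no geometry optimisation.  Central assumptions:

* **Rigid, frozen monomers.**  Monomer electron distributions are computed
  once per unique molecule and never relaxed in the field of the partner.
  Mutual polarization enters only through the perturbative −½α|F|² term.
* **Pairwise additivity.**  Lattice energies are half-sums of pair energies;
  three-body induction and dispersion are absorbed, on average, by the
  fitted scale factors.
* **Calibrated scales.**  The k factors are least-squares fits to
  counterpoise-corrected B3LYP-D2/6-31G(d,p) supermolecule energies, so the
  individual terms are not physical observables; only comparisons within
  one model are meaningful.  Totals are rounded to whole kJ/mol for
  reporting since single-pair accuracy is of order 1–2 kJ/mol at best.

### Electrostatics

E_ele is the exact classical Coulomb energy between the two monomer charge
distributions: nucleus–nucleus, nucleus–electron (both directions) and
electron–electron terms, the latter contracted from two-electron repulsion
integrals over the union (dimer) basis.  For monatomic-ion toy systems a
`PointCharges` monomer gives the closed-form Coulomb limit (e.g. two unit
charges at 8.175 Å → +169.95 kJ/mol).

### Polarization

E_pol = −½ Σ_atoms α |F|², F evaluated at each nucleus of one monomer from
the *total* (nuclear + electronic) charge distribution of the other, both
directions summed.  It is single-shot (non-iterative) and undamped, exactly
as the formula reads.  α are isotropic free-atom polarizabilities; when a
species is unambiguously a bare monatomic ion the much smaller ion value is
used instead (packaged table, atomic units): without this override,
cation-containing pairs acquire polarization energies that are orders of
magnitude too large.  Point-charge probes are non-polarizable by default.

### Dispersion

Grimme's D2 form, E_dis = −s₆ Σ_ij f_dmp(R_ij) C₆ij/R_ij⁶ with
f_dmp(R) = 1/(1+exp(−d(R/R_r−1))), C₆ij = √(C₆i·C₆j), R_r the sum of the
two van der Waals radii, d = 20.  The packaged C₆/R tables are the standard
D2 constants (C₆ in J·nm⁶·mol⁻¹, radii in Å).  s₆ is fixed at 1.0: any
global prefactor is absorbed by the fitted k_dis, so users comparing against
D2-corrected DFT should note the convention.

### Exchange–repulsion

The occupied spin orbitals of the two monomers are pooled on the union
basis, Löwdin symmetric-orthonormalised (per spin block), and the
Hartree–Fock energy expression of that single determinant is evaluated with
the dimer Hamiltonian.  Subtracting the two monomer energies (same
expression, own orbitals) and E_ele leaves the exchange–repulsion component.
Löwdin orthonormalisation is a convention — any orthonormalisation of the
same occupied span yields the same determinant energy, which the test suite
exploits by checking against an independent QR-based construction.

Open shells: monomer SCF is unrestricted, with excess spin in the alpha
block, so pooling two doublets automatically yields the S_z = 1 (triplet)
determinant — the high-spin convention for open-shell pairs.  Odd-electron
species with unspecified multiplicity default to doublets.

For CE-B3LYP monomers the same HF-like expression would be applied to the
Kohn–Sham orbitals (no XC functional is evaluated on the antisymmetrised
determinant); this is a documented convention, not a theorem.

## Electronic-structure backend

The bundled engine is a from-scratch Gaussian-basis integral + SCF code
(McMurchie–Davidson Hermite expansions, Boys function via the confluent
hypergeometric function, DIIS-accelerated RHF/UHF with canonical
orthogonalisation).  Convergence thresholds are 1e-10 hartree on the energy
and 1e-8 on the density, tight enough that component energies quoted to
0.1 kJ/mol are stable.  Unit conventions are pinned once:
1 hartree = 2625.499 kJ/mol, 1 bohr = 0.529177 Å.

Packaged basis sets cover the light elements used by the fixtures (STO-3G;
3-21G for H, He, Li, C, N, O, F; 6-31G(d,p) for H, C, N, O); the basis *rules*
of both models are implemented for every element (CE-HF → 3-21G everywhere;
CE-B3LYP → 6-31G(d,p) for H–Kr, DGDZVP beyond).  Engine correctness is
established by independent oracles in the test suite: closed-form Coulomb
limits, radial-quadrature integration of spherical SCF densities,
brute-force variational minimisation, fixed-point Roothaan iteration, the
variational bound E(H atom) > −0.5 hartree, and point-dipole far-field
behaviour of the computed electric fields.

Hybrid-DFT (B3LYP) monomer wavefunctions are intentionally not part of the
bundled engine; the backend protocol (`register_backend`) is the supported
extension point, and the CE-B3LYP scale factors apply unchanged to
components computed from any backend's monomer orbitals.  Requesting a
CE-B3LYP wavefunction without such a backend raises a clear error.

## Crystal plumbing

* **Bonding criterion**: atoms bonded when d < r_cov(A)+r_cov(B)+0.4 Å
  (Cordero covalent radii).  This reproduces ordinary organic and
  coordination connectivity and cleanly isolates monatomic ions.
* **Molecule perception**: connected components of the bond graph, unwrapped
  across periodic boundaries so every molecule is whole; a site reachable
  from itself under two different lattice offsets signals polymeric or
  framework connectivity, which is refused (the pairwise model is for
  molecular crystals).
* **X—H normalization**: hydrogens are moved along their X—H bond to the
  standard neutron-diffraction lengths C—H 1.083, N—H 1.009, O—H 0.983,
  B—H 1.185 Å; other X—H bonds are left unchanged with a warning.  Heavy
  atoms are never moved.
* **Clusters and unique pairs**: neighbours are whole molecules with any
  atom within the contact radius (default 3.8 Å, a conventional
  nearest-neighbour shell; the value is a package choice, exposed as a CLI
  flag).  Pairs are deduplicated by sorted intermolecular-distance
  fingerprints within 1e-3 Å; enantiomeric contacts with identical
  fingerprints merge, which is exact for all four terms since each is
  invariant under rigid reflection of the pair.
* **Coordinates**: fractional internally for symmetry (in the crystal's own
  cell; no primitive-cell reduction), Cartesian Å for geometry.

## Lattice sums

E_lat = ½ Σ E_tot per molecule, grown in 2 Å shells of centre-of-mass
distance until an occupied shell contributes ≤ tol (default 0.5 kJ/mol) or
r_max (default 30 Å) is reached; non-convergence is flagged and warned, not
silently accepted.  Charged species are refused — ionic lattice sums are
conditionally convergent and need Ewald-type resummation, which is out of
scope.  No tail correction is applied beyond r_max: dispersion tails at
30 Å are far below the model's ~1 kJ/mol reliability.  A pluggable
`energy_fn` supports convergence studies with cheap surrogate energies
(e.g. point-charge models), which is also how the summation is validated
against a 60 Å brute-force half-sum in the tests.

## Energy frameworks

Nodes at centres of mass; cylinder radius = |E|/cylinder_scale (so a larger
"cylinder scale" draws thinner cylinders); edges with |E| below the cutoff
(default 15 kJ/mol) are omitted.  Colours: red = electrostatic,
green = dispersion, blue = total, yellow = destabilizing (positive)
electrostatic/total edges — dispersion is never positive, so never yellow.
The exact geometric meaning of "cylinder scale" in interactive viewers
varies; the linear rule above is this package's explicit convention.  Scenes
export to versioned JSON (lossless round-trip) and OBJ (one prism mesh per
edge).

## Calibration

A single pooled, unweighted, no-intercept OLS fit of reference energies on
the four unscaled components (the model has no constant term, and the
published calibration is a single pooled fit; how ion–ion rows spanning
thousands of kJ/mol should be weighted against neutral rows is genuinely
open — unweighted is the documented choice).  Deviations are model −
reference.  Reported per subset (neutral, organic-salt, metal-organic,
open-shell): N, MAD, MD, RMSD, extreme deviations; parameter correlations
come from the scaled inverse normal-equations matrix.  Box-plot summaries
use linear-interpolation quartiles and whiskers at mean ± 1 SD, with every
deviation beyond the whiskers listed individually as an outlier.
`benchmark_pair_energy` regenerates counterpoise-corrected reference
energies (ghost-atom monomer calculations in the full dimer basis, plus the
intermolecular D2 term) with the bundled HF backend; rows from fallback
sources are tagged via `source_tag`, not auto-detected.

## Synthetic fixtures: what they show and what they do not

The fixture module generates toy crystals (simple-cubic point lattices,
CsCl-type ion pairs, cubic molecular lattices, a P2₁/c molecular crystal, a
zwitterion straddling a cell boundary), rigid template dimers from fixed
literature-standard geometries (e.g. water r(OH) = 0.9572 Å,
∠HOH = 104.52°), and benchmark tables with known scale factors — components
drawn uniformly from subset ranges mimicking the four calibration
categories (the organic-salt block spans |E_ref| up to ~2000 kJ/mol, an
order of magnitude beyond the neutral block) and Gaussian noise at a chosen
σ.  Identical spec + seed gives identical bytes.

Passing tests on these fixtures demonstrate correctness of the machinery —
symmetry handling, perception, term evaluation against independent oracles,
fit recovery — but not chemical accuracy on real crystals: the toy lattices
have no disorder, no Z′ > 1, light elements only, and the synthetic
benchmark tables have uncorrelated regressors, unlike real training sets
where electrostatics and polarization are strongly collinear.  Reproducing
published per-structure energies additionally requires the corresponding
CSD structures and a DFT backend for CE-B3LYP monomer wavefunctions.

## Problem sizes and defaults

The test suite and the acceptance script run on small monomers (H, He, H₂,
HF, H₂O) in the 3-21G basis — union-basis dimers of ≤ 26 functions — which
keeps every integral tensor exact and every check fast.  Key defaults:
contact radius 3.8 Å; fingerprint tolerance 1e-3 Å; lattice shells 2 Å,
tol 0.5 kJ/mol, r_max 30 Å; cylinder scale 150, framework cutoff 15 kJ/mol;
SCF 1e-10/1e-8.  Degenerate inputs are handled explicitly: coincident
nuclei across monomers raise a singularity error, linearly dependent pooled
occupied sets raise with a geometry hint, empty neighbour lists and empty
framework graphs are valid, and near-linear-dependent basis sets are
handled by canonical orthogonalisation with a 1e-10 eigenvalue cut.

## Known limitations

* No DFT in the bundled backend (see above); CE-HF is the turnkey model.
* Polarization is isotropic, atom-centred and undamped; it can overbind at
  very short contacts.
* Ionic lattice energies are out of scope (conditional convergence).
* Disorder, partial occupancy and polymeric solids are rejected rather than
  modelled; hydrogen placement from scratch is not attempted (only X—H
  re-normalization of existing hydrogens).
* Energy frameworks show nearest-neighbour pair energies only, a picture
  that degrades for strongly dipolar molecules and must be used with great
  caution for ionic crystals, where omitted long-range terms are large.
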