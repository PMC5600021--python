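"""Crystal I/O: CIF parsing, symmetry, molecule perception, pair dedup."""

import numpy as np
import pytest

from cepair.crystal_io import (
    CifFormatError,
    Crystal,
    Molecule,
    PolymericStructureError,
    SymmetryOperation,
    UnitCell,
    ValidationError,
    assign_species,
    build_cluster,
    expand_symmetry,
    normalize_xh,
    pair_fingerprint,
    perceive_molecules,
    read_cif,
    unique_pairs,
    write_cif,
)
from cepair.fixtures import FixtureSpec, make_toy_crystal

MINIMAL_P1 = """data_test
_cell_length_a 4.0
_cell_length_b 4.0
_cell_length_c 4.0
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_symmetry_equiv_pos_as_xyz
 'x,y,z'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
 C1 C 0.0 0.0 0.0
"""


class TestReadCif:
    def test_minimal_p1(self, tmp_path):
        path = tmp_path / "p1.cif"
        path.write_text(MINIMAL_P1)
        crystal = read_cif(path)
        assert crystal.nsites == 1
        assert len(crystal.symmetry_ops) == 1
        assert crystal.sites[0][0] == "C"

    def test_p21c_operator_recovery(self, tmp_path):
        """The four P2_1/c operators, applied by hand, must match expansion."""
        path = tmp_path / "p21c.cif"
        make_toy_crystal(FixtureSpec("p21c_molecule"), path=path)
        crystal = read_cif(path)
        assert len(crystal.symmetry_ops) == 4
        # hand-applied operator oracle on one general site
        site = crystal.sites[0][1]
        images = set()
        for op in crystal.symmetry_ops:
            images.add(tuple(np.round(np.mod(op.apply(site), 1.0), 6)))
        assert len(images) == 4
        expanded = expand_symmetry(crystal)
        expanded_positions = {
            tuple(np.round(f, 6))
            for el, f, _ in expanded.sites
            if el == crystal.sites[0][0]
        }
        assert images <= expanded_positions

    def test_missing_cell_length_raises(self, tmp_path):
        path = tmp_path / "bad.cif"
        path.write_text(MINIMAL_P1.replace("_cell_length_a 4.0\n", ""))
        with pytest.raises(CifFormatError, match="_cell_length_a"):
            read_cif(path)

    def test_unknown_element_raises(self, tmp_path):
        path = tmp_path / "bad_el.cif"
        path.write_text(MINIMAL_P1.replace(" C1 C ", " Qq1 Qq "))
        with pytest.raises(ValidationError):
            read_cif(path)

    def test_write_read_round_trip(self, tmp_path):
        path = tmp_path / "w.cif"
        make_toy_crystal(FixtureSpec("p21c_molecule"), path=path)
        crystal = read_cif(path)
        path2 = tmp_path / "rt.cif"
        write_cif(crystal, path2)
        back = read_cif(path2)
        assert back.nsites == crystal.nsites
        for (el1, f1, _), (el2, f2, _) in zip(crystal.sites, back.sites):
            assert el1 == el2
            assert np.allclose(f1, f2, atol=1e-6)


class TestUnitCellAndOps:
    def test_invalid_cell_rejected(self):
        with pytest.raises(ValidationError):
            UnitCell(-1.0, 4.0, 4.0, 90, 90, 90)
        with pytest.raises(ValidationError):
            UnitCell(4.0, 4.0, 4.0, 0.0, 90, 90)

    def test_rotation_determinant_checked(self):
        with pytest.raises(ValidationError):
            SymmetryOperation(rotation=((2, 0, 0), (0, 1, 0), (0, 0, 1)), translation=(0, 0, 0))

    def test_expand_idempotent(self, tmp_path):
        path = tmp_path / "p21c.cif"
        make_toy_crystal(FixtureSpec("p21c_molecule"), path=path)
        crystal = read_cif(path)
        once = expand_symmetry(crystal)
        twice = expand_symmetry(once)
        assert once.nsites == twice.nsites == 4 * crystal.nsites
        for (el1, f1, _), (el2, f2, _) in zip(once.sites, twice.sites):
            assert el1 == el2 and np.allclose(f1, f2, atol=1e-9)


class TestNormalizeXH:
    def _water_crystal(self, r_oh=0.95):
        cell = UnitCell(8.0, 8.0, 8.0, 90, 90, 90)
        ang = np.radians(104.52 / 2)
        atoms = [
            ("O", np.array([4.0, 4.0, 4.0])),
            ("H", np.array([4.0, 4.0 + r_oh * np.sin(ang), 4.0 + r_oh * np.cos(ang)])),
            ("H", np.array([4.0, 4.0 - r_oh * np.sin(ang), 4.0 + r_oh * np.cos(ang)])),
        ]
        sites = [(el, cell.to_fractional(p), f"{el}{i}") for i, (el, p) in enumerate(atoms)]
        return Crystal(cell=cell, symmetry_ops=[], sites=sites)

    def test_oh_set_to_standard_length_direction_kept(self):
        crystal = self._water_crystal(r_oh=0.95)
        out = normalize_xh(crystal)
        cell = crystal.cell
        o = cell.to_cartesian(out.sites[0][1])
        for k in (1, 2):
            h_old = cell.to_cartesian(crystal.sites[k][1])
            h_new = cell.to_cartesian(out.sites[k][1])
            assert np.linalg.norm(h_new - o) == pytest.approx(0.983, abs=1e-10)
            v_old = (h_old - o) / np.linalg.norm(h_old - o)
            v_new = (h_new - o) / np.linalg.norm(h_new - o)
            assert np.allclose(v_old, v_new, atol=1e-10)

    def test_already_normalized_is_fixed_point(self):
        crystal = self._water_crystal(r_oh=0.983)
        out = normalize_xh(crystal)
        for (_, f1, _), (_, f2, _) in zip(crystal.sites, out.sites):
            assert np.allclose(f1, f2, atol=1e-12)

    def test_heavy_atoms_bit_for_bit(self):
        crystal = self._water_crystal()
        out = normalize_xh(crystal)
        assert np.all(out.sites[0][1] == crystal.sites[0][1])

    def test_structure_without_h_unchanged(self, he_crystal):
        out = normalize_xh(he_crystal)
        for (_, f1, _), (_, f2, _) in zip(he_crystal.sites, out.sites):
            assert np.all(f1 == f2)


class TestPerception:
    def test_single_molecule(self, tmp_path):
        path = tmp_path / "w.cif"
        make_toy_crystal(FixtureSpec("molecular_lattice", {"template": "H2O"}), path=path)
        mols = perceive_molecules(read_cif(path))
        assert len(mols) == 1
        assert mols[0].natoms == 3
        assert mols[0].formula == "H2O"

    def test_two_monatomic_species(self, tmp_path):
        path = tmp_path / "rs.cif"
        make_toy_crystal(FixtureSpec("ion_pair_lattice"), path=path)
        mols = perceive_molecules(read_cif(path))
        assert sorted(m.formula for m in mols) == ["Cl", "Na"]
        assert all(m.natoms == 1 for m in mols)

    def test_zwitterion_completed_across_boundary(self, tmp_path):
        """Brute-force supercell component oracle vs periodic perception."""
        path = tmp_path / "z.cif"
        make_toy_crystal(FixtureSpec("zwitterion_split"), path=path)
        crystal = read_cif(path)
        mols = perceive_molecules(crystal)
        assert len(mols) == 1
        assert mols[0].natoms == 10

        # oracle: connected components on an explicit 3x3x3 supercell
        from cepair.constants import BOND_TOLERANCE, COVALENT_RADIUS

        cell = crystal.cell
        atoms = []
        for el, f, _ in crystal.sites:
            for shift in np.ndindex(3, 3, 3):
                atoms.append((el, cell.to_cartesian(f + np.array(shift))))
        n = len(atoms)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                d = np.linalg.norm(atoms[i][1] - atoms[j][1])
                if d < COVALENT_RADIUS[atoms[i][0]] + COVALENT_RADIUS[atoms[j][0]] + BOND_TOLERANCE:
                    parent[find(i)] = find(j)
        sizes = {}
        for i in range(n):
            sizes[find(i)] = sizes.get(find(i), 0) + 1
        # interior components are whole molecules of 10 atoms
        assert max(sizes.values()) == 10

    def test_polymeric_raises(self):
        cell = UnitCell(1.4, 8.0, 8.0, 90, 90, 90)
        crystal = Crystal(
            cell=cell, symmetry_ops=[], sites=[("C", np.zeros(3), "C1")]
        )
        with pytest.raises(PolymericStructureError, match="molecular"):
            perceive_molecules(crystal)

    def test_translation_invariance(self, tmp_path):
        """Shifting all fractional coordinates by a lattice vector yields
        congruent molecules."""
        path = tmp_path / "w.cif"
        make_toy_crystal(FixtureSpec("molecular_lattice", {"template": "H2O"}), path=path)
        crystal = read_cif(path)
        shifted = Crystal(
            cell=crystal.cell,
            symmetry_ops=list(crystal.symmetry_ops),
            sites=[(el, f + np.array([1.0, 0.0, 0.0]), lab) for el, f, lab in crystal.sites],
            spacegroup=crystal.spacegroup,
        )
        m1 = perceive_molecules(crystal)[0]
        m2 = perceive_molecules(shifted)[0]
        # compare sorted intramolecular distances (congruence up to rigid motion)
        d1 = np.sort(pair_fingerprint(m1, m1))
        d2 = np.sort(pair_fingerprint(m2, m2))
        assert np.allclose(d1, d2, atol=1e-8)


class TestAssignSpecies:
    def test_monatomic_cation_flagged(self, tmp_path):
        path = tmp_path / "rs.cif"
        make_toy_crystal(FixtureSpec("ion_pair_lattice"), path=path)
        mols = perceive_molecules(read_cif(path))
        out = assign_species(mols, {"Na": {"charge": 1}, "Cl": {"charge": -1}})
        by_label = {m.label: m for m in out}
        assert by_label["Na"].is_monatomic_ion
        assert by_label["Na"].net_charge == 1
        assert by_label["Cl"].is_monatomic_ion

    def test_closed_shell_default_singlet(self, water_molecule):
        out = assign_species([water_molecule])
        assert out[0].multiplicity == 1

    def test_odd_electron_default_doublet(self):
        no = Molecule([("N", np.zeros(3)), ("O", np.array([0, 0, 1.15]))])
        out = assign_species([no])
        assert out[0].multiplicity == 2

    def test_parity_mismatch_raises(self, water_molecule):
        with pytest.raises(ValidationError, match="multiplicity"):
            assign_species([water_molecule], {"H2O": {"multiplicity": 2}})


class TestClustersAndPairs:
    def test_zero_radius_empty(self, he_crystal):
        mols = assign_species(perceive_molecules(he_crystal))
        assert build_cluster(he_crystal, mols[0], 0.0) == []

    def test_simple_cubic_first_shell(self, he_crystal):
        mols = assign_species(perceive_molecules(he_crystal))
        neighbors = build_cluster(he_crystal, mols[0], 5.1, species=mols)
        assert len(neighbors) == 6

    def test_neighbor_fingerprints_symmetry_invariant(self, he_crystal):
        mols = assign_species(perceive_molecules(he_crystal))
        neighbors = build_cluster(he_crystal, mols[0], 7.2, species=mols)
        fps = sorted(tuple(np.round(pair_fingerprint(mols[0], nb), 6)) for nb in neighbors)
        # 6 at 5.0 and 12 at 5*sqrt(2)
        assert len(neighbors) == 18
        assert len(set(fps)) == 2

    def test_unique_pairs_multiplicity(self, he_crystal):
        mols = assign_species(perceive_molecules(he_crystal))
        neighbors = build_cluster(he_crystal, mols[0], 5.1, species=mols)
        pairs = unique_pairs(mols[0], neighbors)
        assert len(pairs) == 1
        assert pairs[0].multiplicity_count == 6
        assert pairs[0].centroid_distance == pytest.approx(5.0, abs=1e-9)

    def test_multiplicities_sum_to_neighbor_count(self, he_crystal):
        mols = assign_species(perceive_molecules(he_crystal))
        neighbors = build_cluster(he_crystal, mols[0], 8.8, species=mols)
        pairs = unique_pairs(mols[0], neighbors)
        assert sum(p.multiplicity_count for p in pairs) == len(neighbors)

    def test_empty_neighbors(self, water_molecule):
        assert unique_pairs(water_molecule, []) == []

    def test_distinct_fingerprints_stay_separate(self, water_molecule):
        a = water_molecule.translated(np.array([0, 0, 5.0]))
        b = water_molecule.translated(np.array([0, 0, 7.0]))
        pairs = unique_pairs(water_molecule, [a, b])
        assert len(pairs) == 2
        assert all(p.multiplicity_count == 1 for p in pairs)

    def test_fingerprint_swap_invariant(self, water_molecule):
        other = water_molecule.translated(np.array([1.0, 2.0, 3.0]))
        fp_ab = pair_fingerprint(water_molecule, other)
        fp_ba = pair_fingerprint(other, water_molecule)
        assert np.allclose(fp_ab, fp_ba)
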