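import numpy as np
import pytest

from cepair.crystal_io import Molecule, read_cif
from cepair.electronic_structure import CE_HF, compute_wavefunction
from cepair.fixtures import FixtureSpec, make_dimer, make_toy_crystal


@pytest.fixture(scope="session")
def he_lattice_cif(tmp_path_factory):
    path = tmp_path_factory.mktemp("cif") / "he_lattice.cif"
    make_toy_crystal(FixtureSpec("point_lattice", {"element": "He", "a": 5.0}), path=path)
    return path


@pytest.fixture(scope="session")
def he_crystal(he_lattice_cif):
    return read_cif(he_lattice_cif)


@pytest.fixture(scope="session")
def water_molecule():
    mol, _ = make_dimer("H2O", 50.0)
    return mol


@pytest.fixture(scope="session")
def he_dimer_25():
    """He–He at 2.5 Å with converged CE-HF monomer wavefunctions."""
    a, b = make_dimer("He", 2.5)
    return compute_wavefunction(a, CE_HF), compute_wavefunction(b, CE_HF)


@pytest.fixture(scope="session")
def h_radical_dimer():
    """Two hydrogen-atom doublets 2.5 Å apart (CE-HF, unrestricted)."""
    a, b = make_dimer("H_atom", 2.5)
    return compute_wavefunction(a, CE_HF), compute_wavefunction(b, CE_HF)


@pytest.fixture
def unit_point_charge():
    def _make(position, charge=1):
        mol = Molecule(
            [("H", np.asarray(position, dtype=float))],
            net_charge=charge,
            is_monatomic_ion=True,
            multiplicity=1,
        )
        from cepair.electronic_structure import PointCharges

        return PointCharges(mol)

    return _make
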