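"""Physical constants and element tables used across the package.

Unit conventions are fixed once, here: energies in hartree internally for
quantum-mechanical quantities, kJ mol^-1 for reported interaction energies,
Å for geometry (bohr inside integral code).
"""

from __future__ import annotations

# Unit conversions (pinned; all derived quantities use these).
HARTREE_TO_KJMOL = 2625.499
BOHR_TO_ANGSTROM = 0.529177
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM
#: e^2/(4 pi eps0) in kJ mol^-1 Å — Coulomb energy of two unit charges 1 Å apart.
COULOMB_KJMOL_ANGSTROM = HARTREE_TO_KJMOL * BOHR_TO_ANGSTROM  # 1389.3539...

ELEMENTS = [
    "X", "H", "He",
    "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
    "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr",
    "Rb", "Sr", "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd",
    "In", "Sn", "Sb", "Te", "I", "Xe",
    "Cs", "Ba",
]
ATOMIC_NUMBER = {sym: z for z, sym in enumerate(ELEMENTS)}
del ATOMIC_NUMBER["X"]

# Covalent radii in Å (Cordero et al. single-bond compilation); the bonding
# criterion is d(A,B) < r_cov(A) + r_cov(B) + BOND_TOLERANCE.
COVALENT_RADIUS = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Sc": 1.70, "Ti": 1.60, "V": 1.53, "Cr": 1.39,
    "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "Y": 1.90, "Zr": 1.75, "Nb": 1.64, "Mo": 1.54,
    "Tc": 1.47, "Ru": 1.46, "Rh": 1.42, "Pd": 1.39, "Ag": 1.45, "Cd": 1.44,
    "In": 1.42, "Sn": 1.39, "Sb": 1.39, "Te": 1.38, "I": 1.39, "Xe": 1.40,
    "Cs": 2.44, "Ba": 2.15,
}
BOND_TOLERANCE = 0.4  # Å added on top of the covalent-radius sum

# Standard atomic weights (u), for centers of mass.
ATOMIC_MASS = {
    "H": 1.008, "He": 4.0026,
    "Li": 6.94, "Be": 9.0122, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.098, "Ca": 40.078, "Sc": 44.956, "Ti": 47.867, "V": 50.942,
    "Cr": 51.996, "Mn": 54.938, "Fe": 55.845, "Co": 58.933, "Ni": 58.693,
    "Cu": 63.546, "Zn": 65.38,
    "Ga": 69.723, "Ge": 72.630, "As": 74.922, "Se": 78.971, "Br": 79.904,
    "Kr": 83.798,
    "Rb": 85.468, "Sr": 87.62, "Y": 88.906, "Zr": 91.224, "Nb": 92.906,
    "Mo": 95.95, "Tc": 98.0, "Ru": 101.07, "Rh": 102.91, "Pd": 106.42,
    "Ag": 107.87, "Cd": 112.41,
    "In": 114.82, "Sn": 118.71, "Sb": 121.76, "Te": 127.60, "I": 126.90,
    "Xe": 131.29, "Cs": 132.91, "Ba": 137.33,
}

# Standard X—H bond lengths from neutron diffraction (Å); hydrogens are
# riding on X and are moved along the X—H vector to exactly these values.
NEUTRON_XH_BOND_LENGTHS = {"C": 1.083, "N": 1.009, "O": 0.983, "B": 1.185}


def atomic_number(symbol: str) -> int:
    """Atomic number for an element symbol (case-normalised)."""
    sym = symbol.strip().capitalize()
    if sym not in ATOMIC_NUMBER:
        raise ValueError(f"unknown element symbol {symbol!r}")
    return ATOMIC_NUMBER[sym]


def normalize_symbol(symbol: str) -> str:
    sym = symbol.strip().capitalize()
    if sym not in ATOMIC_NUMBER:
        raise ValueError(f"unknown element symbol {symbol!r}")
    return sym
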