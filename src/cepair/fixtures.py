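"""Synthetic inputs: toy crystals, dimers and benchmark tables.

Everything every module needs for testing is generated here, from fixed
literature-standard template geometries and seeded random draws — no
external downloads.  Identical spec + seed always yields identical output
bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import BenchmarkRow
from .crystal_io import Crystal, Molecule, SymmetryOperation, UnitCell, write_cif

__all__ = ["FixtureSpec", "make_toy_crystal", "make_dimer", "make_benchmark_table",
           "TEMPLATES"]

FIXTURE_KINDS = (
    "point_lattice",
    "molecular_lattice",
    "ion_pair_lattice",
    "p21c_molecule",
    "zwitterion_split",
    "benchmark_table",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic fixture."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unsupported fixture kind {self.kind!r}; known: {FIXTURE_KINDS}")


# ---------------------------------------------------------------------------
# molecular templates (fixed standard geometries, Å)

_R_OH, _ANG_HOH = 0.9572, 104.52  # water
_SIN = np.sin(np.radians(_ANG_HOH / 2.0))
_COS = np.cos(np.radians(_ANG_HOH / 2.0))

TEMPLATES: dict[str, dict] = {
    "H2": {"atoms": [("H", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, 0.7414))]},
    "He": {"atoms": [("He", (0.0, 0.0, 0.0))]},
    "H2O": {
        "atoms": [
            ("O", (0.0, 0.0, 0.0)),
            ("H", (0.0, _R_OH * _SIN, _R_OH * _COS)),
            ("H", (0.0, -_R_OH * _SIN, _R_OH * _COS)),
        ]
    },
    "HF": {"atoms": [("H", (0.0, 0.0, 0.0)), ("F", (0.0, 0.0, 0.9168))]},
    "Li+": {"atoms": [("Li", (0.0, 0.0, 0.0))], "charge": 1},
    "F-": {"atoms": [("F", (0.0, 0.0, 0.0))], "charge": -1},
    # doublet radicals
    "H_atom": {"atoms": [("H", (0.0, 0.0, 0.0))], "multiplicity": 2},
    "NO_radical": {
        "atoms": [("N", (0.0, 0.0, 0.0)), ("O", (0.0, 0.0, 1.1508))],
        "multiplicity": 2,
    },
}


def _template_molecule(name: str) -> Molecule:
    if name not in TEMPLATES:
        raise ValueError(f"unknown molecule template {name!r}; known: {sorted(TEMPLATES)}")
    t = TEMPLATES[name]
    mol = Molecule(
        atoms=[(el, np.array(p)) for el, p in t["atoms"]],
        net_charge=t.get("charge", 0),
        multiplicity=t.get("multiplicity", 1),
        is_monatomic_ion=len(t["atoms"]) == 1 and t.get("charge", 0) != 0,
        label=name,
    )
    return mol


def _euler_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Z-Y-Z Euler rotation, angles in degrees."""
    a, b, g = np.radians([alpha, beta, gamma])

    def rz(t):
        return np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]])

    def ry(t):
        return np.array([[np.cos(t), 0, np.sin(t)], [0, 1, 0], [-np.sin(t), 0, np.cos(t)]])

    return rz(a) @ ry(b) @ rz(g)


def make_dimer(
    template: str,
    separation: float,
    orientation: tuple[float, float, float] = (0.0, 0.0, 0.0),
    template_b: str | None = None,
) -> tuple[Molecule, Molecule]:
    """Two rigid template copies: centres of mass ``separation`` Å apart
    along z, the second copy rotated by the Z-Y-Z Euler ``orientation``."""
    if separation <= 0:
        raise ValueError("separation must be positive")
    mol_a = _template_molecule(template)
    mol_b = _template_molecule(template_b or template)
    com_a = mol_a.center_of_mass
    mol_a = mol_a.translated(-com_a)
    R = _euler_matrix(*orientation)
    com_b = mol_b.center_of_mass
    rotated = [(el, R @ (pos - com_b)) for el, pos in mol_b.atoms]
    mol_b = Molecule(
        atoms=rotated,
        net_charge=mol_b.net_charge,
        multiplicity=mol_b.multiplicity,
        is_monatomic_ion=mol_b.is_monatomic_ion,
        label=mol_b.label,
    ).translated(np.array([0.0, 0.0, separation]))
    return mol_a, mol_b


# ---------------------------------------------------------------------------
# toy crystals


def _p1_ops() -> list[SymmetryOperation]:
    return [SymmetryOperation.identity()]


def make_toy_crystal(spec: FixtureSpec, path=None) -> str:
    """Well-formed CIF text for a toy crystal; optionally written to a file.

    Kinds:

    * ``point_lattice`` — one atom per simple-cubic cell (params: ``element``
      default He, ``a`` default 5.0 Å); declared in the full cubic space
      group so symmetry-table lookup is exercised.
    * ``ion_pair_lattice`` — CsCl-type arrangement of two monatomic species
      (params: ``cation`` Na, ``anion`` Cl, ``a`` 4.1 Å).
    * ``molecular_lattice`` — one template molecule per cubic P1 cell
      (params: ``template`` H2O, ``a`` 6.0 Å).
    * ``p21c_molecule`` — one template molecule in a P2_1/c cell (params:
      ``template`` H2O, ``a``/``b``/``c``, ``beta``).
    * ``zwitterion_split`` — a 10-atom glycine-like zwitterion deliberately
      straddling a cell boundary, to exercise molecule completion.
    """
    p = spec.params
    if spec.kind == "point_lattice":
        el = p.get("element", "He")
        a = float(p.get("a", 5.0))
        cell = UnitCell(a, a, a, 90.0, 90.0, 90.0)
        crystal = Crystal(
            cell=cell,
            symmetry_ops=[],
            sites=[(el, np.zeros(3), f"{el}1")],
            spacegroup="P m -3 m",
        )
        text = write_cif(crystal)
        # declare the space group by name only: reading recovers the 48 ops
        text = text.replace(
            "loop_\n_symmetry_equiv_pos_as_xyz\n  'x,y,z'\n", ""
        )
    elif spec.kind == "ion_pair_lattice":
        cat = p.get("cation", "Na")
        an = p.get("anion", "Cl")
        a = float(p.get("a", 4.1))
        cell = UnitCell(a, a, a, 90.0, 90.0, 90.0)
        crystal = Crystal(
            cell=cell,
            symmetry_ops=_p1_ops(),
            sites=[
                (cat, np.zeros(3), f"{cat}1"),
                (an, np.array([0.5, 0.5, 0.5]), f"{an}1"),
            ],
            spacegroup="P 1",
        )
        text = write_cif(crystal)
    elif spec.kind == "molecular_lattice":
        template = p.get("template", "H2O")
        a = float(p.get("a", 6.0))
        mol = _template_molecule(template)
        cell = UnitCell(a, a, a, 90.0, 90.0, 90.0)
        center = cell.to_fractional(mol.center_of_mass)
        sites = []
        for i, (el, pos) in enumerate(mol.atoms):
            frac = cell.to_fractional(pos) - center + 0.5
            sites.append((el, frac, f"{el}{i + 1}"))
        crystal = Crystal(cell=cell, symmetry_ops=_p1_ops(), sites=sites, spacegroup="P 1")
        text = write_cif(crystal)
    elif spec.kind == "p21c_molecule":
        template = p.get("template", "H2O")
        mol = _template_molecule(template)
        cell = UnitCell(
            float(p.get("a", 7.0)),
            float(p.get("b", 8.0)),
            float(p.get("c", 9.0)),
            90.0,
            float(p.get("beta", 102.0)),
            90.0,
        )
        ops = [
            SymmetryOperation.from_xyz(t)
            for t in ("x,y,z", "-x,y+1/2,-z+1/2", "-x,-y,-z", "x,-y+1/2,z+1/2")
        ]
        center = cell.to_fractional(mol.center_of_mass)
        sites = []
        for i, (el, pos) in enumerate(mol.atoms):
            frac = cell.to_fractional(pos) - center + np.array([0.15, 0.10, 0.12])
            sites.append((el, frac, f"{el}{i + 1}"))
        crystal = Crystal(cell=cell, symmetry_ops=ops, sites=sites, spacegroup="P 21/c")
        text = write_cif(crystal)
    elif spec.kind == "zwitterion_split":
        # glycine-like +H3N-CH2-COO- skeleton (idealised geometry), placed so
        # roughly half the atoms fall outside [0,1) and wrap on storage
        a = float(p.get("a", 10.0))
        cell = UnitCell(a, a, a, 90.0, 90.0, 90.0)
        atoms = [
            ("N", (-1.95, 0.00, 0.25)),
            ("H", (-2.30, 0.85, 0.70)),
            ("H", (-2.30, -0.85, 0.70)),
            ("H", (-2.30, 0.00, -0.70)),
            ("C", (-0.45, 0.00, 0.25)),
            ("H", (-0.10, 0.88, 0.80)),
            ("H", (-0.10, -0.88, 0.80)),
            ("C", (0.15, 0.00, -1.15)),
            ("O", (1.39, 0.00, -1.20)),
            ("O", (-0.60, 0.00, -2.12)),
        ]
        sites = []
        for i, (el, pos) in enumerate(atoms):
            frac = cell.to_fractional(np.array(pos))  # wraps modulo 1 on storage
            sites.append((el, frac, f"{el}{i + 1}"))
        crystal = Crystal(cell=cell, symmetry_ops=_p1_ops(), sites=sites, spacegroup="P 1")
        text = write_cif(crystal)
    else:
        raise ValueError(f"fixture kind {spec.kind!r} does not produce a crystal")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# benchmark tables

# Component draw ranges per subset (kJ/mol), mimicking the magnitudes of the
# four calibration categories; the organic-salt block spans ion-ion energies
# an order of magnitude larger than the neutral-pair range.
_SUBSET_RANGES = {
    "neutral": {"e_ele": (-120, 10), "e_pol": (-30, 0), "e_dis": (-60, 0), "e_rep": (0, 120)},
    "organic-salt": {
        "e_ele": (-1800, 1800),
        "e_pol": (-150, 0),
        "e_dis": (-60, 0),
        "e_rep": (0, 200),
    },
    "metal-organic": {
        "e_ele": (-200, 20),
        "e_pol": (-50, 0),
        "e_dis": (-80, 0),
        "e_rep": (0, 150),
    },
    "open-shell": {
        "e_ele": (-250, 50),
        "e_pol": (-60, 0),
        "e_dis": (-60, 0),
        "e_rep": (0, 150),
    },
}


def make_benchmark_table(
    k_true: tuple[float, float, float, float],
    n: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[BenchmarkRow]:
    """Synthetic calibration rows with known scale factors.

    Components are drawn uniformly from subset-specific ranges and
    E_ref = k_true · components + N(0, noise_sd); rows cycle through the
    four subsets so per-subset statistics are exercised.
    """
    if n < 4:
        raise ValueError("at least 4 rows are required for a 4-parameter fit")
    k = np.asarray(k_true, dtype=float)
    if k.shape != (4,):
        raise ValueError("k_true must have exactly 4 factors")
    rng = np.random.default_rng(seed)
    subsets = sorted(_SUBSET_RANGES)
    rows = []
    for i in range(n):
        subset = subsets[i % len(subsets)]
        ranges = _SUBSET_RANGES[subset]
        comp = np.array(
            [rng.uniform(*ranges[name]) for name in ("e_ele", "e_pol", "e_dis", "e_rep")]
        )
        e_ref = float(comp @ k) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        rows.append(
            BenchmarkRow(
                label=f"pair{i:04d}",
                subset=subset,
                e_ele=float(comp[0]),
                e_pol=float(comp[1]),
                e_dis=float(comp[2]),
                e_rep=float(comp[3]),
                e_ref=e_ref,
                source_tag="synthetic",
            )
        )
    return rows
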