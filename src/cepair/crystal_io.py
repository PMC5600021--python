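"""Crystal structures: CIF input, symmetry expansion, molecule perception.

The pipeline implemented here turns a CIF file into whole molecules/ions and
symmetry-unique molecular pairs:

1. :func:`read_cif` — unit cell, explicit symmetry operator list, sites;
2. :func:`normalize_xh` — X—H bond lengths set to standard neutron values;
3. :func:`perceive_molecules` — connected components under a covalent-radius
   bonding criterion, completed across cell boundaries;
4. :func:`assign_species` — formal charges, spin multiplicities and
   monatomic-ion flags from a user config;
5. :func:`build_cluster` / :func:`unique_pairs` — the nearest-neighbour shell
   around a central molecule, deduplicated by interatomic-distance
   fingerprints into symmetry-unique pairs with multiplicities.

Fractional coordinates are used for all symmetry handling (in the crystal's
own cell; no primitive-cell reduction); molecular geometry is Cartesian Å.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .constants import (
    ATOMIC_MASS,
    BOND_TOLERANCE,
    COVALENT_RADIUS,
    NEUTRON_XH_BOND_LENGTHS,
    atomic_number,
    normalize_symbol,
)

__all__ = [
    "UnitCell",
    "SymmetryOperation",
    "Crystal",
    "Molecule",
    "DimerPair",
    "CifFormatError",
    "ValidationError",
    "PolymericStructureError",
    "read_cif",
    "write_cif",
    "expand_symmetry",
    "normalize_xh",
    "perceive_molecules",
    "assign_species",
    "build_cluster",
    "unique_pairs",
    "molecule_fingerprint",
    "pair_fingerprint",
]

DEFAULT_CONTACT_RADIUS = 3.8  # Å, conventional nearest-neighbour shell
DEFAULT_FINGERPRINT_TOL = 1e-3  # Å


class CifFormatError(ValueError):
    pass


class ValidationError(ValueError):
    pass


class PolymericStructureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# core types


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell metric: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise ValidationError(f"cell angle {name} must lie in (0, 180) degrees")
        if self.volume <= 0:
            raise ValidationError("cell volume must be positive")

    @property
    def lattice(self) -> np.ndarray:
        """Column matrix turning fractional into Cartesian coordinates (Å)."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        cx = self.c * np.cos(be)
        cy = self.c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
        cz = np.sqrt(max(self.c**2 - cx**2 - cy**2, 0.0))
        return np.array(
            [
                [self.a, self.b * np.cos(ga), cx],
                [0.0, self.b * np.sin(ga), cy],
                [0.0, 0.0, cz],
            ]
        )

    @property
    def volume(self) -> float:
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        t = (
            1
            - np.cos(al) ** 2
            - np.cos(be) ** 2
            - np.cos(ga) ** 2
            + 2 * np.cos(al) * np.cos(be) * np.cos(ga)
        )
        return self.a * self.b * self.c * np.sqrt(max(t, 0.0))

    def to_cartesian(self, frac) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.lattice.T

    def to_fractional(self, cart) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ np.linalg.inv(self.lattice).T


@dataclass(frozen=True)
class SymmetryOperation:
    """Fractional-coordinate operation x' = R x + t."""

    rotation: tuple  # 3x3 nested tuple of ints (or rational floats)
    translation: tuple  # fractional 3-vector

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if abs(abs(np.linalg.det(R)) - 1.0) > 1e-9:
            raise ValidationError("symmetry rotation must have |det| = 1")

    @property
    def R(self) -> np.ndarray:
        return np.asarray(self.rotation, dtype=float)

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float)

    def apply(self, frac) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.R.T + self.t

    @classmethod
    def from_xyz(cls, triplet: str) -> "SymmetryOperation":
        op = gemmi.Op(triplet)
        R = tuple(tuple(x / gemmi.Op.DEN for x in row) for row in op.rot)
        t = tuple(x / gemmi.Op.DEN for x in op.tran)
        return cls(rotation=R, translation=t)

    def to_xyz(self) -> str:
        op = gemmi.Op()
        den = gemmi.Op.DEN
        op.rot = [[int(round(x * den)) for x in row] for row in np.asarray(self.rotation)]
        op.tran = [int(round(x * den)) for x in self.translation]
        return op.triplet()

    @classmethod
    def identity(cls) -> "SymmetryOperation":
        return cls(rotation=((1, 0, 0), (0, 1, 0), (0, 0, 1)), translation=(0.0, 0.0, 0.0))


@dataclass
class Crystal:
    """Unit cell + explicit symmetry operations + asymmetric-unit sites."""

    cell: UnitCell
    symmetry_ops: list[SymmetryOperation]
    sites: list[tuple[str, np.ndarray, str]]  # (element, fractional position, label)
    spacegroup: str = "P 1"

    def __post_init__(self):
        fixed = []
        for element, frac, label in self.sites:
            sym = normalize_symbol(element)
            fixed.append((sym, np.mod(np.asarray(frac, dtype=float), 1.0), str(label)))
        self.sites = fixed
        if not self.symmetry_ops:
            self.symmetry_ops = [SymmetryOperation.identity()]

    @property
    def nsites(self) -> int:
        return len(self.sites)


@dataclass
class Molecule:
    """A whole molecule/ion: the monomer unit of every energy term."""

    atoms: list[tuple[str, np.ndarray]]  # (element, Cartesian position Å)
    net_charge: int = 0
    multiplicity: int = 1
    is_monatomic_ion: bool = False
    origin: str = "x,y,z + (0,0,0)"
    label: str = ""

    def __post_init__(self):
        self.atoms = [
            (normalize_symbol(el), np.asarray(pos, dtype=float)) for el, pos in self.atoms
        ]
        if not self.label:
            self.label = self.formula

    @property
    def natoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [el for el, _ in self.atoms]

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([pos for _, pos in self.atoms])

    @property
    def formula(self) -> str:
        counts: dict[str, int] = {}
        for el in self.elements:
            counts[el] = counts.get(el, 0) + 1
        # Hill order
        order = []
        if "C" in counts:
            order.append("C")
            if "H" in counts:
                order.append("H")
        order += sorted(el for el in counts if el not in order)
        return "".join(f"{el}{counts[el] if counts[el] > 1 else ''}" for el in order)

    @property
    def n_electrons(self) -> int:
        return sum(atomic_number(el) for el in self.elements) - self.net_charge

    @property
    def center_of_mass(self) -> np.ndarray:
        m = np.array([ATOMIC_MASS[el] for el in self.elements])
        return (m[:, None] * self.coordinates).sum(axis=0) / m.sum()

    def translated(self, shift) -> "Molecule":
        return replace(
            self,
            atoms=[(el, pos + np.asarray(shift, dtype=float)) for el, pos in self.atoms],
        )

    def validate_species(self) -> None:
        n = self.n_electrons
        if n <= 0:
            raise ValidationError(f"{self.label}: no electrons for charge {self.net_charge}")
        if (n - (self.multiplicity - 1)) % 2 != 0 or self.multiplicity < 1:
            raise ValidationError(
                f"{self.label}: multiplicity {self.multiplicity} inconsistent with "
                f"{n} electrons (charge {self.net_charge})"
            )
        if self.is_monatomic_ion and (self.natoms != 1 or self.net_charge == 0):
            raise ValidationError(
                f"{self.label}: monatomic-ion flag requires a single charged atom"
            )


@dataclass
class DimerPair:
    """A symmetry-unique molecule/ion pair with its occurrence multiplicity."""

    molecule_a: Molecule
    molecule_b: Molecule
    centroid_distance: float
    closest_contact: float
    multiplicity_count: int = 1
    fingerprint: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        if self.centroid_distance < 0:
            raise ValidationError("centroid distance must be >= 0")
        if self.multiplicity_count < 1:
            raise ValidationError("multiplicity count must be >= 1")


# ---------------------------------------------------------------------------
# fingerprints


def molecule_fingerprint(mol: Molecule, decimals: int = 6) -> tuple:
    """Congruence key: sorted elements + sorted intramolecular distances."""
    xyz = mol.coordinates
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    upper = np.sort(d[np.triu_indices(len(xyz), k=1)])
    return (tuple(sorted(mol.elements)), tuple(np.round(upper, decimals)))


def pair_fingerprint(mol_a: Molecule, mol_b: Molecule) -> np.ndarray:
    """Sorted list of all intermolecular atom-pair distances (swap-invariant)."""
    d = np.linalg.norm(
        mol_a.coordinates[:, None, :] - mol_b.coordinates[None, :, :], axis=-1
    )
    return np.sort(d.ravel())


# ---------------------------------------------------------------------------
# CIF input / output


def _cif_number(value: str) -> float:
    # strip standard-uncertainty parentheses: "1.234(5)" -> 1.234
    v = value.split("(")[0]
    return float(v)


def read_cif(path) -> Crystal:
    """Read a crystal from a CIF file with explicit symmetry operators.

    Symmetry is taken from ``_symmetry_equiv_pos_as_xyz`` (or the newer
    ``_space_group_symop_operation_xyz``) when present, otherwise from the
    space-group name/number via gemmi's space-group tables.
    """
    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block()

    cell_items = {}
    for key in ("a", "b", "c", "alpha", "beta", "gamma"):
        tag = f"_cell_length_{key}" if key in "abc" else f"_cell_angle_{key}"
        raw = block.find_value(tag)
        if raw is None:
            raise CifFormatError(f"CIF is missing the cell block item {tag}")
        cell_items[key] = _cif_number(raw)
    cell = UnitCell(**cell_items)

    ops: list[SymmetryOperation] = []
    for loop_tag in ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz"):
        col = block.find_loop(loop_tag)
        triplets = [gemmi.cif.as_string(v) for v in col]
        if triplets:
            ops = [SymmetryOperation.from_xyz(t) for t in triplets]
            break
    sg_label = None
    for tag in ("_symmetry_space_group_name_H-M", "_space_group_name_H-M_alt"):
        raw = block.find_value(tag)
        if raw is not None:
            sg_label = gemmi.cif.as_string(raw)
            break
    if not ops:
        sg = None
        if sg_label:
            sg = gemmi.find_spacegroup_by_name(sg_label)
        if sg is None:
            raw = block.find_value("_space_group_IT_number") or block.find_value(
                "_symmetry_Int_Tables_number"
            )
            if raw is not None:
                sg = gemmi.find_spacegroup_by_number(int(gemmi.cif.as_int(raw)))
        if sg is None:
            raise CifFormatError(
                "CIF has neither a symmetry-operator loop nor a recognisable "
                "space-group name/number"
            )
        ops = [SymmetryOperation.from_xyz(op.triplet()) for op in sg.operations()]
        sg_label = sg.hm

    labels = block.find_loop("_atom_site_label")
    xs = block.find_loop("_atom_site_fract_x")
    ys = block.find_loop("_atom_site_fract_y")
    zs = block.find_loop("_atom_site_fract_z")
    if not list(xs):
        raise CifFormatError("CIF is missing the _atom_site loop (fractional coordinates)")
    symbols = [gemmi.cif.as_string(v) for v in block.find_loop("_atom_site_type_symbol")]
    labels = [gemmi.cif.as_string(v) for v in labels]
    if not symbols:
        # derive element from the site label (leading alphabetic characters)
        symbols = []
        for lab in labels:
            head = "".join(ch for ch in lab if ch.isalpha())[:2]
            try:
                symbols.append(normalize_symbol(head))
            except ValueError:
                symbols.append(normalize_symbol(head[:1]))
    sites = []
    for lab, sym, x, y, z in zip(labels, symbols, xs, ys, zs):
        sym = sym.strip().rstrip("+-0123456789")
        try:
            sym = normalize_symbol(sym)
        except ValueError as exc:
            raise ValidationError(str(exc)) from None
        frac = np.array([_cif_number(gemmi.cif.as_string(v)) for v in (x, y, z)])
        sites.append((sym, frac, lab))

    identity = SymmetryOperation.identity()
    if not any(np.allclose(op.R, identity.R) and np.allclose(op.t % 1.0, 0.0) for op in ops):
        ops.insert(0, identity)
    return Crystal(cell=cell, symmetry_ops=ops, sites=sites, spacegroup=sg_label or "P 1")


def write_cif(crystal: Crystal, path=None) -> str:
    """Write a crystal as CIF text (deterministic formatting); optionally to a file."""
    lines = ["data_cepair", f"_symmetry_space_group_name_H-M   '{crystal.spacegroup}'"]
    for key, val in zip(
        ("a", "b", "c"), (crystal.cell.a, crystal.cell.b, crystal.cell.c)
    ):
        lines.append(f"_cell_length_{key}   {val:.6f}")
    for key, val in zip(
        ("alpha", "beta", "gamma"),
        (crystal.cell.alpha, crystal.cell.beta, crystal.cell.gamma),
    ):
        lines.append(f"_cell_angle_{key}   {val:.6f}")
    lines += ["loop_", "_symmetry_equiv_pos_as_xyz"]
    for op in crystal.symmetry_ops:
        lines.append(f"  '{op.to_xyz()}'")
    lines += [
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    for element, frac, label in crystal.sites:
        lines.append(
            f"  {label} {element} {frac[0]:.8f} {frac[1]:.8f} {frac[2]:.8f}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# symmetry expansion


def expand_symmetry(crystal: Crystal, tol: float = 1e-6) -> Crystal:
    """Apply the full operator list; return a P1 cell with unique sites only.

    Idempotent: expanding an already-expanded crystal changes nothing.
    """
    new_sites: list[tuple[str, np.ndarray, str]] = []
    for element, frac, label in crystal.sites:
        for k, op in enumerate(crystal.symmetry_ops):
            img = np.mod(op.apply(frac), 1.0)
            dup = False
            for el2, f2, _ in new_sites:
                if el2 != element:
                    continue
                diff = np.abs(img - f2)
                diff = np.minimum(diff, 1.0 - diff)
                if np.all(diff < tol):
                    dup = True
                    break
            if not dup:
                suffix = f"_{k}" if k else ""
                new_sites.append((element, img, f"{label}{suffix}"))
    return Crystal(
        cell=crystal.cell,
        symmetry_ops=[SymmetryOperation.identity()],
        sites=new_sites,
        spacegroup="P 1",
    )


# ---------------------------------------------------------------------------
# bonding and hydrogen normalization


def _bonded(el_a: str, el_b: str, distance: float) -> bool:
    return distance < COVALENT_RADIUS[el_a] + COVALENT_RADIUS[el_b] + BOND_TOLERANCE


def _neighbor_images(crystal: Crystal):
    """All symmetry+lattice images (element, frac) within the 3x3x3 block."""
    expanded = expand_symmetry(crystal)
    out = []
    for element, frac, label in expanded.sites:
        for n in np.ndindex(3, 3, 3):
            shift = np.array(n) - 1
            out.append((element, frac + shift, label))
    return out


def normalize_xh(crystal: Crystal, bond_table: dict | None = None) -> Crystal:
    """Move each H along its X—H bond so the bond length equals the standard
    neutron-diffraction value for X; heavy atoms are untouched.

    Hydrogens bonded to an element missing from the table are left unchanged
    with a warning, as are hydrogens with no identifiable heavy-atom partner.
    """
    table = NEUTRON_XH_BOND_LENGTHS if bond_table is None else bond_table
    images = [
        (el, crystal.cell.to_cartesian(frac), lab)
        for el, frac, lab in _neighbor_images(crystal)
        if el != "H"
    ]
    new_sites = []
    for element, frac, label in crystal.sites:
        if element != "H":
            new_sites.append((element, frac, label))
            continue
        pos = crystal.cell.to_cartesian(frac)
        partners = [
            (np.linalg.norm(pos - xyz), el, xyz)
            for el, xyz, _ in images
            if _bonded("H", el, np.linalg.norm(pos - xyz))
        ]
        if not partners:
            warnings.warn(f"H site {label} has no bonded heavy atom; left unchanged")
            new_sites.append((element, frac, label))
            continue
        partners.sort(key=lambda t: t[0])
        if len(partners) > 1:
            warnings.warn(
                f"H site {label} is within bonding distance of {len(partners)} heavy "
                "atoms; using the nearest"
            )
        dist, heavy_el, heavy_xyz = partners[0]
        if heavy_el not in table:
            warnings.warn(
                f"no standard X—H length for element {heavy_el}; H site {label} unchanged"
            )
            new_sites.append((element, frac, label))
            continue
        direction = (pos - heavy_xyz) / dist
        new_pos = heavy_xyz + direction * table[heavy_el]
        new_frac = np.mod(crystal.cell.to_fractional(new_pos), 1.0)
        new_sites.append((element, new_frac, label))
    return Crystal(
        cell=crystal.cell,
        symmetry_ops=list(crystal.symmetry_ops),
        sites=new_sites,
        spacegroup=crystal.spacegroup,
    )


# ---------------------------------------------------------------------------
# molecule perception


def _unit_cell_molecules(crystal: Crystal) -> list[Molecule]:
    """All whole molecules whose seed atom lies in the unit cell.

    Connected components of the bond graph, unwrapped across periodic
    boundaries so each molecule is geometrically contiguous.  Raises
    :class:`PolymericStructureError` for infinite (framework) connectivity.
    """
    expanded = expand_symmetry(crystal)
    frac = np.array([f for _, f, _ in expanded.sites])
    elements = [el for el, _, _ in expanded.sites]
    labels = [lab for _, _, lab in expanded.sites]
    n = len(frac)
    lattice = crystal.cell.lattice

    # neighbour list over the 27 surrounding cells
    shifts = [np.array(s) - 1 for s in np.ndindex(3, 3, 3)]
    molecules: list[Molecule] = []
    seen = [False] * n
    for seed in range(n):
        if seen[seed]:
            continue
        # BFS with unwrapped lattice offsets per visited (site, offset)
        offsets: dict[int, np.ndarray] = {seed: np.zeros(3)}
        queue = [seed]
        seen[seed] = True
        while queue:
            i = queue.pop()
            pos_i = (frac[i] + offsets[i]) @ lattice.T
            for j in range(n):
                for s in shifts:
                    off_j = offsets[i] + s
                    pos_j = (frac[j] + off_j) @ lattice.T
                    d = np.linalg.norm(pos_i - pos_j)
                    if d < 1e-4:  # same atom (or a wrapped image of it)
                        continue
                    if _bonded(elements[i], elements[j], d):
                        if j in offsets:
                            if not np.allclose(offsets[j], off_j, atol=1e-6):
                                raise PolymericStructureError(
                                    "bond network extends infinitely (polymeric or "
                                    "framework solid); the pairwise model applies to "
                                    "molecular crystals only"
                                )
                        else:
                            offsets[j] = off_j
                            seen[j] = True
                            queue.append(j)
        atom_ids = sorted(offsets)
        atoms = [
            (elements[i], (frac[i] + offsets[i]) @ lattice.T) for i in atom_ids
        ]
        molecules.append(
            Molecule(atoms=atoms, origin=f"{labels[seed]} + (0,0,0)")
        )
    return molecules


def perceive_molecules(crystal: Crystal, unique: bool = True) -> list[Molecule]:
    """Whole molecules in the unit cell; one representative per congruence
    class when ``unique`` (the default)."""
    mols = _unit_cell_molecules(crystal)
    if not unique:
        return mols
    seen: dict[tuple, Molecule] = {}
    counts: dict[str, int] = {}
    out = []
    for mol in mols:
        key = molecule_fingerprint(mol, decimals=4)
        if key in seen:
            continue
        seen[key] = mol
        base = mol.formula
        counts[base] = counts.get(base, 0) + 1
        label = base if counts[base] == 1 else f"{base}_{counts[base]}"
        mol.label = label
        out.append(mol)
    # disambiguate first occurrence if duplicates appeared later
    for mol in out:
        if counts.get(mol.formula, 0) > 1 and mol.label == mol.formula:
            mol.label = f"{mol.formula}_1"
    return out


def assign_species(molecules: list[Molecule], config: dict | None = None) -> list[Molecule]:
    """Apply charge/multiplicity assignments and flag monatomic ions.

    ``config`` maps a molecule label (or formula) to
    ``{"charge": int, "multiplicity": int}``.  Defaults: neutral; singlet for
    even electron counts, doublet for odd.
    """
    config = config or {}
    out = []
    for mol in molecules:
        entry = config.get(mol.label) or config.get(mol.formula) or {}
        charge = int(entry.get("charge", 0))
        n_elec = sum(atomic_number(el) for el in mol.elements) - charge
        default_mult = 1 if n_elec % 2 == 0 else 2
        mult = int(entry.get("multiplicity", default_mult))
        new = replace(
            mol,
            net_charge=charge,
            multiplicity=mult,
            is_monatomic_ion=(mol.natoms == 1 and charge != 0),
        )
        new.validate_species()
        out.append(new)
    return out


# ---------------------------------------------------------------------------
# clusters and unique pairs


def _congruent_transfer(mol: Molecule, template: Molecule) -> Molecule:
    """Copy species attributes (charge, multiplicity, flags) from a congruent
    template molecule onto a freshly generated image."""
    return replace(
        mol,
        net_charge=template.net_charge,
        multiplicity=template.multiplicity,
        is_monatomic_ion=template.is_monatomic_ion,
        label=template.label,
    )


def build_cluster(
    crystal: Crystal,
    central: Molecule,
    contact_radius: float = DEFAULT_CONTACT_RADIUS,
    species: list[Molecule] | None = None,
) -> list[Molecule]:
    """All whole molecules with any atom within ``contact_radius`` of any atom
    of ``central`` (the central molecule itself excluded).

    ``species`` (typically the output of :func:`assign_species`) supplies
    charges/multiplicities for the generated neighbours by congruence.
    """
    if contact_radius < 0:
        raise ValidationError("contact radius must be >= 0")
    base_mols = _unit_cell_molecules(crystal)
    if species:
        keyed = {molecule_fingerprint(m, decimals=4): m for m in species}
        base_mols = [
            _congruent_transfer(m, keyed[molecule_fingerprint(m, decimals=4)])
            if molecule_fingerprint(m, decimals=4) in keyed
            else m
            for m in base_mols
        ]
    lattice = crystal.cell.lattice
    central_xyz = central.coordinates
    # translation search range from radius + molecular extents
    extent = max(
        (np.linalg.norm(m.coordinates - m.center_of_mass, axis=1).max() if m.natoms > 1 else 0.0)
        for m in base_mols
    )
    central_extent = (
        np.linalg.norm(central_xyz - central.center_of_mass, axis=1).max()
        if central.natoms > 1
        else 0.0
    )
    reach = contact_radius + extent + central_extent
    # conservative integer ranges per lattice direction
    inv = np.linalg.inv(lattice)
    nmax = [int(np.ceil(reach * np.linalg.norm(inv[:, k]))) + 1 for k in range(3)]
    neighbors = []
    for mol in base_mols:
        for n in np.ndindex(*(2 * m + 1 for m in nmax)):
            shift = (np.array(n) - nmax) @ lattice.T
            cand_xyz = mol.coordinates + shift
            d = np.linalg.norm(central_xyz[:, None, :] - cand_xyz[None, :, :], axis=-1)
            dmin = d.min()
            if dmin < 1e-4:  # the central molecule itself
                continue
            if contact_radius > 0 and dmin <= contact_radius:
                cand = mol.translated(shift)
                cand.origin = f"{mol.origin.split(' + ')[0]} + ({n[0]-nmax[0]},{n[1]-nmax[1]},{n[2]-nmax[2]})"
                neighbors.append(cand)
    return neighbors


def unique_pairs(
    central: Molecule,
    neighbors: list[Molecule],
    tol: float = DEFAULT_FINGERPRINT_TOL,
) -> list[DimerPair]:
    """Group neighbours into symmetry-unique pairs by distance-fingerprint
    equality within ``tol``; the multiplicities sum to the neighbour count."""
    if tol <= 0:
        raise ValidationError("fingerprint tolerance must be positive")
    groups: list[DimerPair] = []
    for nb in neighbors:
        fp = pair_fingerprint(central, nb)
        placed = False
        for pair in groups:
            if len(pair.fingerprint) == len(fp) and np.max(np.abs(pair.fingerprint - fp)) < tol:
                pair.multiplicity_count += 1
                placed = True
                break
        if not placed:
            groups.append(
                DimerPair(
                    molecule_a=central,
                    molecule_b=nb,
                    centroid_distance=float(
                        np.linalg.norm(central.center_of_mass - nb.center_of_mass)
                    ),
                    closest_contact=float(fp[0]),
                    multiplicity_count=1,
                    fingerprint=fp,
                )
            )
    return groups
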