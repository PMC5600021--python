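"""Pairwise lattice-energy summation for crystals of neutral molecules.

The lattice energy per molecule is half the converged sum of pairwise model
energies between one molecule and all others in the crystal,

    E_lat = 1/2 * sum_B E_tot(A, B),

grown in shells of centroid distance until a shell contributes less than a
tolerance.  Ionic lattice sums are conditionally convergent and refused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .crystal_io import (
    Crystal,
    Molecule,
    ValidationError,
    _unit_cell_molecules,
    assign_species,
    molecule_fingerprint,
    pair_fingerprint,
    perceive_molecules,
)
from .electronic_structure import WavefunctionCache, compute_wavefunction
from .energy_terms import (
    CE_HF_MODEL,
    DispersionParams,
    EnergyModel,
    PolarizabilityTable,
    pair_energy,
)

__all__ = ["LatticeSumResult", "lattice_energy", "DEFAULT_SHELL_STEP", "DEFAULT_TOL", "DEFAULT_RMAX"]

DEFAULT_SHELL_STEP = 2.0  # Å of centroid distance per shell
DEFAULT_TOL = 0.5  # kJ/mol
DEFAULT_RMAX = 30.0  # Å


@dataclass
class LatticeSumResult:
    """Converged (or flagged-partial) lattice energy with its shell series."""

    energy: float  # kJ/mol per molecule (Z'-weighted over unique molecules)
    shells: list = field(default_factory=list)  # (radius Å, cumulative kJ/mol)
    tolerance: float = DEFAULT_TOL
    converged: bool = True
    r_max: float = DEFAULT_RMAX
    per_molecule: dict = field(default_factory=dict)  # label -> energy

    def shell_table(self) -> str:
        lines = ["radius_angstrom,cumulative_kjmol"]
        for r, e in self.shells:
            lines.append(f"{r:.1f},{e:.4f}")
        return "\n".join(lines)


def _neighbor_images(crystal: Crystal, central: Molecule, base_mols, r_max: float):
    """(molecule, centroid distance) for every image within r_max of central."""
    lattice = crystal.cell.lattice
    inv = np.linalg.inv(lattice)
    c0 = central.center_of_mass
    out = []
    nmax = [int(np.ceil((r_max + 2.0) * np.linalg.norm(inv[:, k]))) + 1 for k in range(3)]
    for mol in base_mols:
        com = mol.center_of_mass
        for n in np.ndindex(*(2 * m + 1 for m in nmax)):
            shift = (np.array(n) - nmax) @ lattice.T
            d = float(np.linalg.norm(com + shift - c0))
            if d < 1e-4:
                continue  # central molecule itself
            if d <= r_max:
                out.append((mol.translated(shift), d))
    return out


def lattice_energy(
    crystal: Crystal,
    model: EnergyModel = CE_HF_MODEL,
    r_max: float = DEFAULT_RMAX,
    tol: float = DEFAULT_TOL,
    config: dict | None = None,
    energy_fn=None,
    shell_step: float = DEFAULT_SHELL_STEP,
) -> LatticeSumResult:
    """Converged pairwise lattice energy per molecule (kJ/mol).

    ``energy_fn(mol_a, mol_b) -> kJ/mol`` overrides the full model energy
    (e.g. a point-charge-only energy for convergence studies).  Symmetry-
    equivalent neighbours are deduplicated by distance fingerprint, so each
    unique pair is evaluated once.
    """
    if tol <= 0 or r_max <= 0 or shell_step <= 0:
        raise ValidationError("tol, r_max and shell_step must be positive")
    species = assign_species(perceive_molecules(crystal), config)
    charged = [m.label for m in species if m.net_charge != 0]
    if charged:
        raise ValidationError(
            f"charged species present ({', '.join(charged)}): ionic lattice sums are "
            "conditionally convergent and are not attempted"
        )
    base_mols = _unit_cell_molecules(crystal)
    keyed = {molecule_fingerprint(m, decimals=4): m for m in species}
    copies = {m.label: 0 for m in species}
    enriched = []
    for m in base_mols:
        key = molecule_fingerprint(m, decimals=4)
        tmpl = keyed.get(key)
        if tmpl is not None:
            m = Molecule(
                atoms=m.atoms,
                net_charge=tmpl.net_charge,
                multiplicity=tmpl.multiplicity,
                is_monatomic_ion=tmpl.is_monatomic_ion,
                origin=m.origin,
                label=tmpl.label,
            )
            copies[tmpl.label] += 1
        enriched.append(m)

    cache = WavefunctionCache()
    polar = PolarizabilityTable()
    disp = DispersionParams()

    def default_energy(mol_a: Molecule, mol_b: Molecule) -> float:
        wa = compute_wavefunction(mol_a, model.theory, cache=cache)
        wb = compute_wavefunction(mol_b, model.theory, cache=cache)
        return pair_energy(wa, wb, model=model, polarizabilities=polar, dispersion=disp).e_tot

    efn = energy_fn or default_energy

    per_molecule = {}
    shell_series = None
    all_converged = True
    for central in species:
        neighbors = _neighbor_images(crystal, central, enriched, r_max)
        neighbors.sort(key=lambda t: t[1])
        # unique-pair energy cache by distance fingerprint
        groups: list[tuple[np.ndarray, float]] = []

        def group_energy(nb: Molecule) -> float:
            fp = pair_fingerprint(central, nb)
            for gfp, ge in groups:
                if len(gfp) == len(fp) and np.max(np.abs(gfp - fp)) < 1e-3:
                    return ge
            ge = efn(central, nb)
            groups.append((fp, ge))
            return ge

        shells = []
        cumulative = 0.0
        converged = False
        r = shell_step
        idx = 0
        while r <= r_max + 1e-9:
            increment = 0.0
            occupied = False
            while idx < len(neighbors) and neighbors[idx][1] <= r:
                nb, _ = neighbors[idx]
                increment += 0.5 * group_energy(nb)
                occupied = True
                idx += 1
            cumulative += increment
            shells.append((r, cumulative))
            # converged once an occupied shell contributes below tolerance
            if occupied and abs(increment) <= tol:
                converged = True
                break
            r += shell_step
        per_molecule[central.label] = cumulative
        if shell_series is None:
            shell_series = shells
        if not converged:
            warnings.warn(
                f"lattice sum for {central.label} not converged to {tol} kJ/mol "
                f"at r_max = {r_max} Å; result flagged partial"
            )
        all_converged = all_converged and converged
    weights = np.array([max(copies.get(m.label, 1), 1) for m in species], dtype=float)
    energies = np.array([per_molecule[m.label] for m in species])
    total = float(np.sum(weights * energies) / np.sum(weights))
    return LatticeSumResult(
        energy=total,
        shells=shell_series or [],
        tolerance=tol,
        converged=all_converged,
        r_max=r_max,
        per_molecule=per_molecule,
    )
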