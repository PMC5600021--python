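"""Restricted and unrestricted Hartree–Fock with DIIS convergence.

Tight defaults (1e-10 hartree on the energy, 1e-8 on the density) because the
interaction-energy components downstream are quoted to 0.1 kJ mol^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..constants import ANGSTROM_TO_BOHR, atomic_number
from .basis import BasisSet
from .integrals import IntegralEngine


class ScfError(RuntimeError):
    pass


class ScfConvergenceError(ScfError):
    def __init__(self, message: str, iterations: int, last_denergy: float, last_ddensity: float):
        super().__init__(
            f"{message} (iterations={iterations}, |dE|={last_denergy:.3e}, "
            f"|dD|={last_ddensity:.3e})"
        )
        self.iterations = iterations
        self.last_denergy = last_denergy
        self.last_ddensity = last_ddensity


@dataclass
class ScfResult:
    energy: float  # hartree, includes nuclear repulsion
    c_alpha: np.ndarray  # MO coefficients (all), alpha block
    c_beta: np.ndarray
    n_alpha: int
    n_beta: int
    overlap: np.ndarray
    hcore: np.ndarray
    basis: BasisSet
    engine: IntegralEngine
    restricted: bool
    iterations: int

    @property
    def density_alpha(self) -> np.ndarray:
        C = self.c_alpha[:, : self.n_alpha]
        return C @ C.T

    @property
    def density_beta(self) -> np.ndarray:
        C = self.c_beta[:, : self.n_beta]
        return C @ C.T

    @property
    def density(self) -> np.ndarray:
        return self.density_alpha + self.density_beta


def nuclear_repulsion(charges: np.ndarray, coords_bohr: np.ndarray) -> float:
    e = 0.0
    for i in range(len(charges)):
        for j in range(i):
            e += charges[i] * charges[j] / np.linalg.norm(coords_bohr[i] - coords_bohr[j])
    return e


def hf_energy_expression(
    h: np.ndarray, eri: np.ndarray, Pa: np.ndarray, Pb: np.ndarray, e_nuc: float
) -> float:
    """Hartree–Fock energy of a (not necessarily self-consistent) spin density.

    Used both by the SCF loop and by the antisymmetrised-product
    exchange–repulsion construction, where the determinant is built from
    frozen monomer orbitals.
    """
    P = Pa + Pb
    J = np.einsum("pqrs,rs->pq", eri, P)
    Ka = np.einsum("prqs,rs->pq", eri, Pa)
    Kb = np.einsum("prqs,rs->pq", eri, Pb)
    e1 = np.sum(P * h)
    e2 = 0.5 * (np.sum(P * J) - np.sum(Pa * Ka) - np.sum(Pb * Kb))
    return e1 + e2 + e_nuc


class _Diis:
    def __init__(self, max_vec: int = 8):
        self.errors: list[np.ndarray] = []
        self.focks: list[np.ndarray] = []
        self.max_vec = max_vec

    def update(self, fock: np.ndarray, error: np.ndarray) -> np.ndarray:
        self.focks.append(fock.copy())
        self.errors.append(error.ravel().copy())
        if len(self.focks) > self.max_vec:
            self.focks.pop(0)
            self.errors.pop(0)
        m = len(self.focks)
        if m < 2:
            return fock
        B = -np.ones((m + 1, m + 1))
        B[m, m] = 0.0
        for i in range(m):
            for j in range(m):
                B[i, j] = self.errors[i] @ self.errors[j]
        rhs = np.zeros(m + 1)
        rhs[m] = -1.0
        try:
            coef = np.linalg.solve(B, rhs)[:m]
        except np.linalg.LinAlgError:
            return fock
        return sum(c * F for c, F in zip(coef, self.focks))


def run_scf(
    atoms: list[tuple[str, np.ndarray]],
    charge: int,
    multiplicity: int,
    basis_rule,
    ghosts: list[tuple[str, np.ndarray]] = (),
    restricted: bool | None = None,
    conv_energy: float = 1e-10,
    conv_density: float = 1e-8,
    max_iterations: int = 300,
) -> ScfResult:
    """Converge an SCF wavefunction for a molecule at a fixed geometry.

    ``ghosts`` carry basis functions without nuclear charge (counterpoise
    calculations).  ``restricted=None`` selects RHF for singlets, UHF
    otherwise.
    """
    charges = np.array([atomic_number(el) for el, _ in atoms], dtype=float)
    coords = np.array([np.asarray(p, dtype=float) for _, p in atoms]) * ANGSTROM_TO_BOHR
    nelec = int(charges.sum()) - charge
    if nelec <= 0:
        raise ScfError(f"no electrons (total nuclear charge {charges.sum()}, charge {charge})")
    if (nelec - (multiplicity - 1)) % 2 != 0 or multiplicity < 1:
        raise ValueError(
            f"multiplicity {multiplicity} inconsistent with {nelec} electrons"
        )
    n_alpha = (nelec + multiplicity - 1) // 2
    n_beta = nelec - n_alpha
    if restricted is None:
        restricted = multiplicity == 1
    if restricted and n_alpha != n_beta:
        raise ValueError(
            f"restricted SCF requested for an open-shell species "
            f"(multiplicity {multiplicity}); use an unrestricted method"
        )

    basis = BasisSet.build(list(atoms) + list(ghosts), basis_rule)
    engine = IntegralEngine(basis)
    S = engine.overlap()
    T = engine.kinetic()
    V = engine.point_charge_potential(charges, coords)
    h = T + V
    eri = engine.eri()
    e_nuc = nuclear_repulsion(charges, coords)

    # canonical orthogonalisation guards against near-linear-dependence
    evals, evecs = np.linalg.eigh(S)
    keep = evals > 1e-10
    X = evecs[:, keep] / np.sqrt(evals[keep])

    def solve(F):
        Fp = X.T @ F @ X
        e, Cp = np.linalg.eigh(Fp)
        return X @ Cp

    Ca = solve(h)
    Cb = Ca.copy()
    Pa = Ca[:, :n_alpha] @ Ca[:, :n_alpha].T
    Pb = Cb[:, :n_beta] @ Cb[:, :n_beta].T

    diis_a, diis_b = _Diis(), _Diis()
    e_old, d_e, d_d = 0.0, 1.0, 1.0
    for it in range(1, max_iterations + 1):
        P = Pa + Pb
        J = np.einsum("pqrs,rs->pq", eri, P)
        Ka = np.einsum("prqs,rs->pq", eri, Pa)
        Kb = np.einsum("prqs,rs->pq", eri, Pb)
        Fa = h + J - Ka
        Fb = h + J - Kb
        energy = 0.5 * (np.sum(P * h) + np.sum(Pa * Fa) + np.sum(Pb * Fb)) + e_nuc

        err_a = Fa @ Pa @ S - S @ Pa @ Fa
        err_b = Fb @ Pb @ S - S @ Pb @ Fb
        Fa = diis_a.update(Fa, err_a)
        Fb = diis_b.update(Fb, err_b)

        Ca = solve(Fa)
        Cb = Ca if restricted else solve(Fb)
        Pa_new = Ca[:, :n_alpha] @ Ca[:, :n_alpha].T
        Pb_new = Cb[:, :n_beta] @ Cb[:, :n_beta].T
        d_e = abs(energy - e_old)
        d_d = max(np.abs(Pa_new - Pa).max(), np.abs(Pb_new - Pb).max())
        Pa, Pb, e_old = Pa_new, Pb_new, energy
        if it > 1 and d_e < conv_energy and d_d < conv_density:
            return ScfResult(
                energy=energy,
                c_alpha=Ca,
                c_beta=Cb,
                n_alpha=n_alpha,
                n_beta=n_beta,
                overlap=S,
                hcore=h,
                basis=basis,
                engine=engine,
                restricted=restricted,
                iterations=it,
            )
    raise ScfConvergenceError("SCF failed to converge", max_iterations, d_e, d_d)
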