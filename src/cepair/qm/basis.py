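"""Gaussian basis sets: packaged data, shell construction, Cartesian functions.

Basis data are shipped as JSON under ``cepair/data/basis`` keyed by the
conventional basis names.  Shells are contracted Cartesian Gaussians; each
Cartesian component is individually normalised (the auto-normalisation is
applied by the integral engine from the raw overlap diagonal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from ..constants import ANGSTROM_TO_BOHR, normalize_symbol

_BASIS_FILES = {
    "STO-3G": "sto-3g.json",
    "3-21G": "3-21g.json",
    "6-31G(d,p)": "6-31g_dp.json",
}

_df = {0: 1.0, 1: 1.0, 2: 3.0, 3: 15.0, 4: 105.0}  # (2n-1)!!


def double_factorial(n: int) -> float:
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


@dataclass(frozen=True)
class Shell:
    """One contracted shell of Cartesian Gaussians on a single center."""

    l: int
    exponents: tuple[float, ...]
    coefficients: tuple[float, ...]  # contraction coefs for normalised primitives
    center: tuple[float, float, float]  # bohr
    atom_index: int

    @property
    def cartesian_powers(self) -> list[tuple[int, int, int]]:
        powers = []
        for i in range(self.l, -1, -1):
            for j in range(self.l - i, -1, -1):
                powers.append((i, j, self.l - i - j))
        return powers

    @property
    def nfunctions(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2


def primitive_norm(alpha: float, l: int) -> float:
    """Normalisation constant of a primitive (l,0,0) Cartesian Gaussian."""
    return (
        (2.0 * alpha / np.pi) ** 0.75
        * (4.0 * alpha) ** (l / 2.0)
        / np.sqrt(double_factorial(2 * l - 1))
    )


class BasisSetError(ValueError):
    pass


def _load_basis_table(name: str) -> dict:
    try:
        fname = _BASIS_FILES[name]
    except KeyError:
        raise BasisSetError(
            f"unknown basis set {name!r}; packaged sets: {sorted(_BASIS_FILES)}"
        ) from None
    text = resources.files("cepair.data.basis").joinpath(fname).read_text()
    return json.loads(text)


_TABLE_CACHE: dict[str, dict] = {}


def basis_shells_for_element(element: str, basis_name: str) -> list[dict]:
    """Raw shell dictionaries (l, exponents, coefficients) for one element."""
    if basis_name not in _TABLE_CACHE:
        _TABLE_CACHE[basis_name] = _load_basis_table(basis_name)
    table = _TABLE_CACHE[basis_name]["elements"]
    sym = normalize_symbol(element)
    if sym not in table:
        raise BasisSetError(
            f"no packaged {basis_name} basis for element {sym}; "
            f"available elements: {sorted(table)}"
        )
    return table[sym]


@dataclass
class BasisSet:
    """A concrete basis: shells placed on atomic (or ghost) centers."""

    shells: list[Shell] = field(default_factory=list)

    @property
    def nbf(self) -> int:
        return sum(sh.nfunctions for sh in self.shells)

    @property
    def function_shells(self) -> list[tuple[Shell, tuple[int, int, int]]]:
        out = []
        for sh in self.shells:
            for powers in sh.cartesian_powers:
                out.append((sh, powers))
        return out

    def function_centers(self) -> np.ndarray:
        return np.array([sh.center for sh, _ in self.function_shells])

    @classmethod
    def build(
        cls,
        atoms: list[tuple[str, np.ndarray]],
        basis_rule,
        atom_offset: int = 0,
    ) -> "BasisSet":
        """Place shells on ``atoms`` = [(element, cartesian position in Å)].

        ``basis_rule`` maps an element symbol to a basis-set name (a plain
        string is accepted and used for every element).  Ghost centers carry
        the same basis functions; the element symbol decides the shells, the
        caller decides whether the nuclear charge is present.
        """
        shells: list[Shell] = []
        for i, (element, pos) in enumerate(atoms):
            name = basis_rule if isinstance(basis_rule, str) else basis_rule(element)
            center = tuple(np.asarray(pos, dtype=float) * ANGSTROM_TO_BOHR)
            for raw in basis_shells_for_element(element, name):
                exps = tuple(float(x) for x in raw["exponents"])
                coefs = tuple(
                    float(c) * primitive_norm(float(a), int(raw["l"]))
                    for a, c in zip(raw["exponents"], raw["coefficients"])
                )
                shells.append(
                    Shell(
                        l=int(raw["l"]),
                        exponents=exps,
                        coefficients=coefs,
                        center=center,
                        atom_index=atom_offset + i,
                    )
                )
        return cls(shells=shells)

    def __add__(self, other: "BasisSet") -> "BasisSet":
        return BasisSet(shells=list(self.shells) + list(other.shells))
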