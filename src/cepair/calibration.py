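"""Calibration of the four scale factors against benchmark pair energies.

The scale factors are obtained from a single unweighted ordinary
least-squares fit, with no intercept, of counterpoise-corrected reference
interaction energies on the four unscaled model components; deviations are
defined as model - reference.  Fit statistics (MAD, MD, RMSD, extreme
deviations) are reported overall and per subset, together with the
parameter correlation matrix from the scaled inverse normal-equations
matrix.

Follows the Model -> fit() -> Results pattern: build a
:class:`ScaleFactorModel` from rows or a DataFrame, call :meth:`fit`, and
inspect the returned :class:`ScaleFactorFit` (or print its ``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .energy_terms import DispersionParams, e_dispersion
from .electronic_structure import TheorySpec, CE_HF
from .constants import HARTREE_TO_KJMOL
from .crystal_io import Molecule
from .qm import run_scf

__all__ = [
    "BenchmarkRow",
    "FitStatistics",
    "BoxplotStats",
    "ScaleFactorModel",
    "ScaleFactorFit",
    "fit_scale_factors",
    "parameter_correlation",
    "fit_statistics",
    "boxplot_stats",
    "benchmark_pair_energy",
    "read_benchmark_csv",
    "write_benchmark_csv",
]

COMPONENT_NAMES = ("e_ele", "e_pol", "e_dis", "e_rep")
PARAMETER_NAMES = ("k_ele", "k_pol", "k_dis", "k_rep")


@dataclass
class BenchmarkRow:
    """One calibration pair: unscaled components + reference energy (kJ/mol)."""

    label: str
    subset: str  # neutral | organic-salt | metal-organic | open-shell
    e_ele: float
    e_pol: float
    e_dis: float
    e_rep: float
    e_ref: float
    source_tag: str = "B3LYP-D2"

    def __post_init__(self):
        vals = [self.e_ele, self.e_pol, self.e_dis, self.e_rep, self.e_ref]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"benchmark row {self.label!r} contains non-finite energies")


class FitStatistics(NamedTuple):
    n: int
    mad: float
    md: float
    rmsd: float
    min_dev: float
    max_dev: float


def fit_statistics(deviations) -> FitStatistics:
    """MAD = mean |d|, MD = mean d, RMSD = sqrt(mean d^2), min/max deviation."""
    d = np.asarray(deviations, dtype=float)
    if d.size == 0:
        raise ValueError("no deviations supplied")
    return FitStatistics(
        n=int(d.size),
        mad=float(np.mean(np.abs(d))),
        md=float(np.mean(d)),
        rmsd=float(np.sqrt(np.mean(d * d))),
        min_dev=float(d.min()),
        max_dev=float(d.max()),
    )


@dataclass
class BoxplotStats:
    """Box-and-whisker summary with whiskers at mean ± one standard deviation."""

    q1: float
    median: float
    q3: float
    mean: float
    sd: float
    outliers: list = dc_field(default_factory=list)

    @property
    def whisker_low(self) -> float:
        return self.mean - self.sd

    @property
    def whisker_high(self) -> float:
        return self.mean + self.sd


def boxplot_stats(groups: dict) -> dict:
    """Per-group box statistics; outliers are exactly the deviations beyond
    mean ± one SD.  Quartiles use linear interpolation."""
    out = {}
    for name, values in groups.items():
        d = np.asarray(values, dtype=float)
        if d.size == 0:
            raise ValueError(f"group {name!r} is empty")
        mean = float(d.mean())
        sd = float(d.std(ddof=0))
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        outliers = sorted(float(x) for x in d[(d < mean - sd) | (d > mean + sd)])
        out[name] = BoxplotStats(
            q1=float(q1), median=float(med), q3=float(q3), mean=mean, sd=sd, outliers=outliers
        )
    return out


class ScaleFactorModel:
    """OLS model E_ref ~ k_ele*E_ele + k_pol*E_pol + k_dis*E_dis + k_rep*E_rep."""

    def __init__(self, rows: list[BenchmarkRow]):
        if len(rows) < 4:
            raise ValueError("at least 4 benchmark rows are required")
        self.rows = list(rows)
        self.X = np.array([[r.e_ele, r.e_pol, r.e_dis, r.e_rep] for r in rows])
        self.y = np.array([r.e_ref for r in rows])
        self.subsets = np.array([r.subset for r in rows])
        rank = np.linalg.matrix_rank(self.X)
        if rank < 4:
            # name the offending columns for the error message
            bad = []
            for j, name in enumerate(COMPONENT_NAMES):
                others = np.delete(self.X, j, axis=1)
                if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(self.X):
                    bad.append(name)
            raise np.linalg.LinAlgError(
                f"regressor matrix is rank deficient (rank {rank} < 4); "
                f"collinear/degenerate columns: {', '.join(bad) or 'undetermined'}"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ScaleFactorModel":
        rows = [
            BenchmarkRow(
                label=str(r.get("label", i)),
                subset=str(r.get("subset", "neutral")),
                e_ele=float(r["e_ele"]),
                e_pol=float(r["e_pol"]),
                e_dis=float(r["e_dis"]),
                e_rep=float(r["e_rep"]),
                e_ref=float(r["e_ref"]),
                source_tag=str(r.get("source_tag", "B3LYP-D2")),
            )
            for i, r in df.iterrows()
        ]
        return cls(rows)

    def fit(self) -> "ScaleFactorFit":
        XtX = self.X.T @ self.X
        k = np.linalg.solve(XtX, self.X.T @ self.y)
        deviations = self.X @ k - self.y  # model - reference
        dof = max(len(self.y) - 4, 1)
        sigma2 = float(deviations @ deviations) / dof
        cov = sigma2 * np.linalg.inv(XtX)
        dd = np.sqrt(np.diag(cov))
        corr = cov / np.outer(dd, dd)
        stats = {"all": fit_statistics(deviations)}
        for subset in sorted(set(self.subsets)):
            stats[subset] = fit_statistics(deviations[self.subsets == subset])
        return ScaleFactorFit(
            k_ele=float(k[0]),
            k_pol=float(k[1]),
            k_dis=float(k[2]),
            k_rep=float(k[3]),
            covariance=cov,
            correlation=corr,
            deviations=deviations,
            subset_labels=self.subsets,
            statistics=stats,
        )


@dataclass
class ScaleFactorFit:
    """Fitted scale factors with uncertainties, statistics and diagnostics."""

    k_ele: float
    k_pol: float
    k_dis: float
    k_rep: float
    covariance: np.ndarray
    correlation: np.ndarray
    deviations: np.ndarray
    subset_labels: np.ndarray
    statistics: dict

    @property
    def params(self) -> np.ndarray:
        return np.array([self.k_ele, self.k_pol, self.k_dis, self.k_rep])

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of the four scale factors."""
        return np.sqrt(np.diag(self.covariance))

    def boxplot_stats(self) -> dict:
        groups = {"all": self.deviations}
        for subset in sorted(set(self.subset_labels)):
            groups[subset] = self.deviations[self.subset_labels == subset]
        return boxplot_stats(groups)

    def summary(self) -> str:
        lines = ["Scale-factor fit (OLS, no intercept; deviations = model - reference)", ""]
        lines.append("  ".join(f"{n:>8s}" for n in PARAMETER_NAMES))
        lines.append("  ".join(f"{v:8.3f}" for v in self.params))
        lines.append("  ".join(f"({s:6.3f})" for s in self.bse))
        lines.append("")
        lines.append("Correlation matrix")
        for i, name in enumerate(PARAMETER_NAMES):
            row = "  ".join(f"{self.correlation[i, j]:6.3f}" for j in range(i + 1))
            lines.append(f"{name:>8s}  {row}")
        lines.append("")
        lines.append(
            f"{'subset':>15s} {'N':>6s} {'MAD':>8s} {'MD':>8s} {'RMSD':>8s} "
            f"{'min':>8s} {'max':>8s}"
        )
        for subset, s in self.statistics.items():
            lines.append(
                f"{subset:>15s} {s.n:6d} {s.mad:8.2f} {s.md:8.2f} {s.rmsd:8.2f} "
                f"{s.min_dev:8.1f} {s.max_dev:8.1f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "scale_factors": dict(zip(PARAMETER_NAMES, self.params.tolist())),
            "standard_errors": dict(zip(PARAMETER_NAMES, self.bse.tolist())),
            "correlation_matrix": self.correlation.tolist(),
            "statistics": {
                name: dict(s._asdict()) for name, s in self.statistics.items()
            },
        }


def fit_scale_factors(rows: list[BenchmarkRow]) -> ScaleFactorFit:
    """Single pooled OLS fit of the four scale factors (no intercept)."""
    return ScaleFactorModel(rows).fit()


def parameter_correlation(rows: list[BenchmarkRow]) -> np.ndarray:
    """4x4 correlation matrix of the fitted scale factors."""
    return ScaleFactorModel(rows).fit().correlation


# ---------------------------------------------------------------------------
# counterpoise-corrected reference energies


def benchmark_pair_energy(
    mol_a: Molecule,
    mol_b: Molecule,
    theory: TheorySpec = CE_HF,
    dispersion: DispersionParams | None = None,
) -> float:
    """Counterpoise-corrected supermolecule interaction energy + D2, kJ/mol.

    E = E(AB; dimer basis) - E(A; ghosts on B) - E(B; ghosts on A) + E_D2,
    each SCF in the full dimer basis.  Open-shell monomers are coupled
    high-spin (two doublets -> triplet).  Provided so calibration reference
    energies can be regenerated with the bundled Hartree-Fock backend.
    """
    if theory.method != "hf":
        raise ValueError(
            "the bundled backend computes Hartree-Fock reference energies; "
            "register a DFT backend for B3LYP-D2 references"
        )
    mult_ab = (mol_a.multiplicity - 1) + (mol_b.multiplicity - 1) + 1  # high spin
    charge_ab = mol_a.net_charge + mol_b.net_charge
    restricted_ab = mult_ab == 1

    e_ab = run_scf(
        atoms=mol_a.atoms + mol_b.atoms,
        charge=charge_ab,
        multiplicity=mult_ab,
        basis_rule=theory.basis_for,
        restricted=restricted_ab,
    ).energy
    e_a = run_scf(
        atoms=mol_a.atoms,
        charge=mol_a.net_charge,
        multiplicity=mol_a.multiplicity,
        basis_rule=theory.basis_for,
        ghosts=mol_b.atoms,
        restricted=mol_a.multiplicity == 1,
    ).energy
    e_b = run_scf(
        atoms=mol_b.atoms,
        charge=mol_b.net_charge,
        multiplicity=mol_b.multiplicity,
        basis_rule=theory.basis_for,
        ghosts=mol_a.atoms,
        restricted=mol_b.multiplicity == 1,
    ).energy
    e_int = (e_ab - e_a - e_b) * HARTREE_TO_KJMOL
    return e_int + e_dispersion(mol_a, mol_b, params=dispersion)


# ---------------------------------------------------------------------------
# CSV schema


def read_benchmark_csv(path) -> list[BenchmarkRow]:
    """Read rows from the benchmark CSV schema
    (label, subset, e_ele, e_pol, e_dis, e_rep, e_ref[, source_tag])."""
    return ScaleFactorModel.from_dataframe(pd.read_csv(path)).rows


def write_benchmark_csv(rows: list[BenchmarkRow], path) -> None:
    df = pd.DataFrame(
        [
            {
                "label": r.label,
                "subset": r.subset,
                "e_ele": r.e_ele,
                "e_pol": r.e_pol,
                "e_dis": r.e_dis,
                "e_rep": r.e_rep,
                "e_ref": r.e_ref,
                "source_tag": r.source_tag,
            }
            for r in rows
        ]
    )
    df.to_csv(path, index=False)
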