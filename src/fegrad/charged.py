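"""Charged-solute hydration free-energy corrections and bookkeeping.

Raw charging free energies from periodic simulations with approximate
electrostatics are methodology-dependent.  The standard hydration free
energy of an ion is assembled from the raw charging + cavitation result
plus correction terms:

    dG_hyd_std = (dG_chg_raw + dG_cav) + dG_ABD + dG_C1 + dG_std,

where dG_ABD collects the type A (approximate electrostatics), B (finite
size) and D (model permittivity) corrections from continuum electrostatics,
dG_C1 converts the implied P-summation (atom-based cutoff) to M-summation
(molecule-based cutoff), and dG_std is the standard-state convention term
(7.95 kJ/mol at 298.15 K and 1 atm).

For fitting, correction *gradients* with respect to the force-field
parameters enter the corrected reference data: requiring equal corrected
free energies for the reference and coarse-grained models, and moving
everything known to the reference side,

    corrected ref gradient = raw ref gradient + ref correction gradient
                             - CG correction gradient.

The correction derivatives are evaluated by central finite differences on
an alpha-scaled parameter set (alpha in [0.4, 1.0]; at alpha = 0.9 the
parameters are at 90% of their value).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol

import numpy as np
import pandas as pd

from .forcefield import ParameterSpace
from .objective import TargetSpec
from .toysim import COULOMB, KB

#: molar gas constant in J/mol/K (SI) and kJ/mol/K
R_SI = 8.3144621
R_KJ = KB

#: Wigner self-interaction constant for a cubic lattice.
XI_WIGNER = -2.837297


def standard_state_term(T: float = 298.15, pressure: float = 101325.0,
                        concentration: float = 1.0,
                        v_gas: float | None = None,
                        v_sol: float | None = None) -> float:
    """Standard-state convention term dG_std = RT ln(v_gas / v_sol), kJ/mol.

    ``v_gas`` is the ideal-gas molar volume at ``pressure`` (Pa) and
    ``v_sol`` the solution standard-state volume 1/concentration (L/mol);
    either may be overridden directly (test hook).  At 298.15 K and 1 atm
    this evaluates to ~7.93 kJ/mol, the conventional ~7.95 kJ/mol figure.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if pressure <= 0 or concentration <= 0:
        raise ValueError("pressure and concentration must be positive")
    if v_gas is None:
        v_gas = R_SI * T / pressure * 1e3  # L/mol
    if v_sol is None:
        v_sol = 1.0 / concentration        # L/mol
    return R_KJ * T * math.log(v_gas / v_sol)


@dataclass(frozen=True)
class CorrectionSet:
    """Correction components for one charged solute (kJ/mol).

    ``dg_std`` is stored alongside but kept out of ``total``: the A+B+D
    and C1 terms correct the charging free energy, while the standard-state
    term is a convention entering only the final assembly.
    """

    dg_abd: float
    dg_c1: float
    dg_std: float
    provenance: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        """dG_cor = dG_ABD + dG_C1 (the charging-correction sum)."""
        return self.dg_abd + self.dg_c1


@dataclass(frozen=True)
class HFEBudget:
    """Audit record of a standard-HFE assembly: every addend plus the sum."""

    raw_plus_cav: float
    dg_abd: float
    dg_c1: float
    dg_std: float

    @property
    def total(self) -> float:
        return self.raw_plus_cav + self.dg_abd + self.dg_c1 + self.dg_std

    def addends(self) -> dict[str, float]:
        return {"raw_plus_cav": self.raw_plus_cav, "dG_ABD": self.dg_abd,
                "dG_C1": self.dg_c1, "dG_std": self.dg_std,
                "dG_hyd_std": self.total}


def assemble_standard_hfe(raw_chg_plus_cav: float,
                          corrections: CorrectionSet) -> HFEBudget:
    """Assemble dG_hyd_std from the raw result and its corrections."""
    vals = [raw_chg_plus_cav, corrections.dg_abd, corrections.dg_c1,
            corrections.dg_std]
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("all budget components must be finite")
    return HFEBudget(raw_plus_cav=raw_chg_plus_cav,
                     dg_abd=corrections.dg_abd, dg_c1=corrections.dg_c1,
                     dg_std=corrections.dg_std)


def charging_free_energy(raw_chg: float, corrections: CorrectionSet) -> float:
    """Methodology-independent charging term dG_chg = dG_chg_raw + dG_cor."""
    return raw_chg + corrections.total


# -- continuum correction providers ---------------------------------------


class ContinuumProvider(Protocol):
    """Contract for the A+B+D correction from continuum electrostatics.

    Implementations must be deterministic and finite-difference
    differentiable in their inputs, return 0 for a neutral solute, and
    (for the packaged default) scale as q^2.
    """

    def dg_abd(self, q: float, radius: float, box_edge: float,
               eps_model: float, eps_exp: float, scheme: str = "LS") -> float:
        ...


@dataclass(frozen=True)
class BornWignerProvider:
    """Analytic Born-ion + Wigner lattice-sum stand-in for the numerical
    Poisson calculations (synthetic; labelled as such).

    The permittivity (type D-like) part is the Born solvation difference
    between the model and experimental dielectric for a cavity of radius
    ``radius``; the finite-size (type B-like) part is the Wigner
    self-interaction energy of a point charge in a cubic periodic box
    screened by the model permittivity.  Coefficients are configurable so
    user-supplied continuum results can be mimicked.
    """

    born_scale: float = 1.0
    wigner_scale: float = 1.0

    def dg_abd(self, q: float, radius: float, box_edge: float,
               eps_model: float, eps_exp: float, scheme: str = "LS") -> float:
        if radius <= 0 or box_edge <= 0:
            raise ValueError("radius and box edge must be positive")
        if eps_model <= 0 or eps_exp <= 0:
            raise ValueError("permittivities must be positive")
        born = -(COULOMB * q * q / (2.0 * radius)) * (1.0 / eps_model
                                                      - 1.0 / eps_exp)
        wigner = COULOMB * XI_WIGNER * q * q / (2.0 * eps_model * box_edge)
        return self.born_scale * born + self.wigner_scale * wigner


def analytic_c1_correction(q: float, quadrupole_trace: float,
                           number_density: float) -> float:
    """Non-authoritative analytic helper for the C1 (P- to M-summation)
    correction, proportional to -q * (solvent quadrupole trace) * density.

    The authoritative C1 values for real systems are user-supplied; this
    helper exists so toy systems can exercise the bookkeeping.
    """
    return -(2.0 * math.pi / 3.0) * COULOMB * q * quadrupole_trace \
        * number_density


# -- correction gradients via alpha-scaled parameters ----------------------


def correction_gradient(correction_fn: Callable[[np.ndarray], float],
                        space: ParameterSpace,
                        alphas: np.ndarray,
                        rel_step: float = 1e-4, abs_floor: float = 1e-6,
                        alpha_range: tuple[float, float] = (0.4, 1.0)
                        ) -> pd.DataFrame:
    """Derivatives of a correction with respect to unscaled parameters.

    For each alpha the correction is evaluated at the parameter set scaled
    to ``alpha * K`` (at alpha = 0.9 parameters are at 90% of their value)
    and central-differenced with respect to each unscaled unfrozen
    parameter: d/dK_i Cor(alpha K) at fixed alpha.  Returns a table with
    one row per alpha and one ``dcor_<name>`` column per parameter, plus
    the steps used.
    """
    alphas = np.asarray(alphas, float)
    lo, hi = alpha_range
    if np.any((alphas < lo) | (alphas > hi)):
        raise ValueError(f"alpha values must lie within [{lo}, {hi}]")
    free = space.free_indices
    K = space.K0
    rows = []
    for a in alphas:
        row: dict[str, float] = {"alpha": float(a)}
        for i in free:
            h = max(abs_floor, rel_step * abs(K[i]))
            Kp, Km = K.copy(), K.copy()
            Kp[i] += h
            Km[i] -= h
            fp = correction_fn(a * Kp)
            fm = correction_fn(a * Km)
            if not (math.isfinite(fp) and math.isfinite(fm)):
                raise ValueError(
                    f"correction provider returned non-finite value near "
                    f"{space.names[i]} at alpha={a:g}")
            row[f"dcor_{space.names[i]}"] = (fp - fm) / (2.0 * h)
            row[f"step_{space.names[i]}"] = h
        rows.append(row)
    return pd.DataFrame(rows)


# -- corrected fitting data (charged targets) ------------------------------


@dataclass(frozen=True)
class ChargedTarget:
    """Corrected reference gradients for a charged solute.

    corrected = raw_ref + cor_ref - cor_cg, per alpha (and per parameter
    direction when the tables carry parameter columns).  Component tables
    are retained for audit.
    """

    alphas: np.ndarray
    corrected: np.ndarray
    raw_ref: np.ndarray
    cor_ref: np.ndarray
    cor_cg: np.ndarray

    def as_target_spec(self, molecule: str, stage: str,
                       ref_se: np.ndarray | None = None,
                       **kwargs) -> TargetSpec:
        se = np.zeros_like(self.corrected) if ref_se is None else ref_se
        return TargetSpec(molecule=molecule, stage=stage, alphas=self.alphas,
                          ref_mean=self.corrected, ref_se=se, **kwargs)


def charged_fit_reference(alphas: np.ndarray, raw_ref: np.ndarray,
                          cor_ref: np.ndarray, cor_cg: np.ndarray
                          ) -> ChargedTarget:
    """Assemble the corrected reference data for a charged-solute fit."""
    alphas = np.asarray(alphas, float)
    arrays = [np.asarray(x, float) for x in (raw_ref, cor_ref, cor_cg)]
    for arr in arrays:
        if arr.shape != alphas.shape:
            raise ValueError("all gradient tables must share the alpha grid")
    raw_ref, cor_ref, cor_cg = arrays
    return ChargedTarget(alphas=alphas, corrected=raw_ref + cor_ref - cor_cg,
                         raw_ref=raw_ref, cor_ref=cor_ref, cor_cg=cor_cg)


# -- packaged reference budgets -------------------------------------------

BUDGET_COLUMNS = ["system", "force_field", "expt", "raw_plus_cav", "raw_se",
                  "dG_ABD", "dG_C1", "dG_std", "dG_hyd"]


def load_reference_budgets() -> pd.DataFrame:
    """Published charged side-chain HFE budgets (kJ/mol) shipped with the
    package: per system and force field, the raw+cavitation result, the
    A+B+D and C1 corrections, the standard-state term, and the printed
    standard HFE total."""
    ref = importlib.resources.files("fegrad.data") / "charged_sidechain_budgets.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


def save_budgets(df: pd.DataFrame, path: str | Path) -> None:
    """Write a correction-budget table in the packaged CSV schema."""
    missing = [c for c in BUDGET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"budget table missing columns: {missing}")
    with open(path, "w") as fh:
        fh.write("# fegrad charged-solute hydration free-energy budgets "
                 "(kJ/mol)\n")
        df[BUDGET_COLUMNS].to_csv(fh, index=False)


def assemble_budget_row(row: pd.Series) -> HFEBudget:
    """Run the standard assembly on one reference-budget row."""
    cor = CorrectionSet(dg_abd=float(row["dG_ABD"]), dg_c1=float(row["dG_C1"]),
                        dg_std=float(row["dG_std"]),
                        provenance={"dg_abd": "user-supplied",
                                    "dg_c1": "user-supplied",
                                    "dg_std": "user-supplied"})
    return assemble_standard_hfe(float(row["raw_plus_cav"]), cor)
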