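"""Ionization and 1:1 drug-cyclodextrin complexation equilibria.

This module covers the solution chemistry of an ionizable drug in the
presence of a cyclodextrin-type solubilizing ligand:

* Henderson-Hasselbalch neutral (unionized) fraction ``f_0`` for
  monoprotic acids and bases;
* the 1:1 binding equilibrium ``D + L <-> DL`` with stability constant
  ``K_1:1`` (1/M), solved in closed form from the mass balances;
* Higuchi-Connors phase-solubility analysis of an A_L-type (linear)
  diagram, yielding ``K_1:1`` and the complexation efficiency CE.

Concentrations entering the binding math are molar; mass/volume inputs
are converted at the I/O boundary with the molecular weights carried by
:class:`CompoundSpec` and :class:`LigandSpec`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


class IonizationClass(str, enum.Enum):
    """Monoprotic ionization behaviour of the compound."""

    MONOPROTIC_BASE = "monoprotic_base"
    MONOPROTIC_ACID = "monoprotic_acid"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class CompoundSpec:
    """Molecular identity of the permeant drug.

    Parameters
    ----------
    name : str
        Compound label.
    molecular_weight : float
        Monomer molecular weight, g/mol.
    pKa : float or None
        Acid dissociation constant exponent; required unless the compound
        is ``NEUTRAL``.
    ionization_class : IonizationClass
        Monoprotic acid, monoprotic base, or neutral.
    solubility_by_medium : mapping
        Medium label -> equilibrium solubility in ug/mL.
    """

    name: str
    molecular_weight: float
    ionization_class: IonizationClass = IonizationClass.NEUTRAL
    pKa: float | None = None
    solubility_by_medium: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")
        ion = IonizationClass(self.ionization_class)
        object.__setattr__(self, "ionization_class", ion)
        if ion is not IonizationClass.NEUTRAL and self.pKa is None:
            raise ValueError("pKa required for ionizable compounds")
        for medium, s in self.solubility_by_medium.items():
            if s <= 0:
                raise ValueError(f"solubility for medium {medium!r} must be positive")

    def solubility(self, medium: str) -> float:
        return self.solubility_by_medium[medium]


@dataclass(frozen=True)
class LigandSpec:
    """Complexing agent identity (e.g. a hydroxypropyl-beta-cyclodextrin)."""

    name: str
    molecular_weight: float

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")


@dataclass(frozen=True)
class PhaseSolubilityDataset:
    """A phase-solubility diagram: drug solubility vs. ligand concentration.

    Both axes are molar. A strictly increasing ligand grid with at least
    three levels is required.
    """

    ligand_concentrations: tuple[float, ...]
    measured_solubilities: tuple[float, ...]
    temperature: float = 37.0
    medium: str = ""
    polymorph: str = ""

    def __post_init__(self) -> None:
        lig = tuple(float(x) for x in self.ligand_concentrations)
        sol = tuple(float(x) for x in self.measured_solubilities)
        object.__setattr__(self, "ligand_concentrations", lig)
        object.__setattr__(self, "measured_solubilities", sol)
        if len(lig) != len(sol):
            raise ValueError("ligand and solubility arrays must have equal length")
        if len(lig) < 3:
            raise ValueError("at least 3 points are required")
        if any(x < 0 for x in lig) or any(x < 0 for x in sol):
            raise ValueError("concentrations must be non-negative")
        if any(b <= a for a, b in zip(lig, lig[1:])):
            raise ValueError("ligand concentrations must be strictly increasing")


@dataclass(frozen=True)
class PhaseSolubilityFit:
    """Linear (A_L-type) phase-solubility fit and derived constants."""

    slope: float
    intercept: float
    r_squared: float
    K_1to1: float
    CE: float
    S_0: float


@dataclass(frozen=True)
class SpeciationState:
    """Solution speciation of drug and ligand at one set of totals (molar)."""

    free_drug: float
    complexed_drug: float
    free_ligand: float
    unbound_fraction: float
    neutral_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("free_drug", "complexed_drug", "free_ligand"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.unbound_fraction <= 1.0 + 1e-12:
            raise ValueError("unbound_fraction must lie in [0, 1]")
        if not 0.0 <= self.neutral_fraction <= 1.0:
            raise ValueError("neutral_fraction must lie in [0, 1]")


def neutral_fraction(
    pKa: float | None,
    pH: float,
    ionization_class: IonizationClass | str = IonizationClass.MONOPROTIC_BASE,
) -> float:
    """Unionized fraction ``f_0`` of a monoprotic compound at a given pH.

    For a monoprotic base ``f_0 = 1 / (1 + 10**(pKa - pH))``; for an acid
    ``f_0 = 1 / (1 + 10**(pH - pKa))``; a neutral compound returns 1.
    """
    ion = IonizationClass(ionization_class)
    if ion is IonizationClass.NEUTRAL:
        return 1.0
    if pKa is None:
        raise ValueError("pKa required for ionizable compounds")
    if ion is IonizationClass.MONOPROTIC_BASE:
        exponent = pKa - pH
    else:
        exponent = pH - pKa
    return 1.0 / (1.0 + 10.0**exponent)


def solve_binding_equilibrium(
    total_drug: float, total_ligand: float, K_1to1: float
) -> SpeciationState:
    """Solve the 1:1 binding equilibrium for the free-drug concentration.

    The stability constant is ``K = [DL] / ([D][L])``. Writing ``x`` for
    free drug, the mass balances give the quadratic

        K*x**2 + (K*(L_tot - D_tot) + 1)*x - D_tot = 0,

    whose positive root in ``[0, D_tot]`` is taken (numerically stable
    form, avoiding cancellation for small K). All concentrations molar.
    ``f_u`` is 1 by convention when ``total_drug`` is 0.
    """
    if total_drug < 0 or total_ligand < 0 or K_1to1 < 0:
        raise ValueError("totals and K must be non-negative")
    d_tot, l_tot, k = float(total_drug), float(total_ligand), float(K_1to1)
    if k == 0.0 or d_tot == 0.0 or l_tot == 0.0:
        free = d_tot
    else:
        b = k * (l_tot - d_tot) + 1.0
        # stable root of K x^2 + b x - D = 0: x = 2D / (b + sqrt(b^2 + 4KD))
        free = 2.0 * d_tot / (b + math.sqrt(b * b + 4.0 * k * d_tot))
    complexed = d_tot - free
    f_u = free / d_tot if d_tot > 0 else 1.0
    return SpeciationState(
        free_drug=free,
        complexed_drug=complexed,
        free_ligand=max(l_tot - complexed, 0.0),
        unbound_fraction=min(f_u, 1.0),
    )


def stability_constant(S_0: float, slope: float) -> float:
    """1:1 stability constant from an A_L-type phase-solubility diagram.

    ``K = slope / (S_0 * (1 - slope))`` with ``S_0`` the intrinsic
    (ligand-free) solubility in molar and ``slope`` the dimensionless
    diagram slope. A slope >= 1 is not an A_L diagram and is rejected.
    """
    if S_0 <= 0:
        raise ValueError("S_0 must be positive")
    if not 0.0 <= slope < 1.0:
        raise ValueError("slope must lie in [0, 1) for an A_L-type diagram")
    return slope / (S_0 * (1.0 - slope))


def complexation_efficiency(S_0: float, K_1to1: float) -> float:
    """Complexation efficiency ``CE = S_0 * K`` (== slope/(1-slope))."""
    if S_0 < 0 or K_1to1 < 0:
        raise ValueError("inputs must be non-negative")
    return S_0 * K_1to1


def unbound_fraction_from_solubility(S_buffer: float, S_CD: float) -> float:
    """Unbound fraction from the plain-buffer / with-ligand solubility ratio.

    ``f_u = S_buffer / S_CD``: solubilization by 1:1 complexation raises
    total solubility while the free-drug concentration stays pinned at
    ``S_buffer``, so the ratio is the equilibrium free fraction.
    """
    if S_buffer <= 0:
        raise ValueError("S_buffer must be positive")
    if S_CD < S_buffer:
        raise ValueError("solubility with ligand cannot be below S_buffer")
    return S_buffer / S_CD


def fit_phase_solubility(
    data: PhaseSolubilityDataset, S_0: float | None = None
) -> PhaseSolubilityFit:
    """Fit an A_L-type phase-solubility diagram by ordinary least squares.

    ``K_1:1`` and CE are derived from the fitted slope together with the
    *measured* intrinsic solubility ``S_0`` (molar); by default S_0 is the
    measured solubility at zero ligand if the diagram includes it, else
    the regression intercept (reported for diagnostics either way).
    """
    lig = np.asarray(data.ligand_concentrations, dtype=float)
    sol = np.asarray(data.measured_solubilities, dtype=float)
    if np.ptp(lig) == 0:
        raise ValueError("zero variance in ligand concentration")
    res = stats.linregress(lig, sol)
    slope = float(res.slope)
    intercept = float(res.intercept)
    r_squared = float(res.rvalue**2)
    if S_0 is None:
        S_0 = sol[0] if lig[0] == 0.0 else intercept
    S_0 = float(S_0)
    if 0.0 <= slope < 1.0 and S_0 > 0:
        K = stability_constant(S_0, slope)
    else:
        K = math.nan
    CE = complexation_efficiency(S_0, K) if math.isfinite(K) else math.nan
    return PhaseSolubilityFit(
        slope=slope, intercept=intercept, r_squared=r_squared, K_1to1=K, CE=CE, S_0=S_0
    )


def phase_solubility_line(S_0: float, K_1to1: float, ligand: Sequence[float]) -> np.ndarray:
    """Exact A_L line ``S(L) = S_0 + [K*S_0/(1 + K*S_0)] * L`` (molar)."""
    lig = np.asarray(ligand, dtype=float)
    slope = K_1to1 * S_0 / (1.0 + K_1to1 * S_0)
    return S_0 + slope * lig
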