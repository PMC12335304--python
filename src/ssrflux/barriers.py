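"""Permeability bookkeeping for the UWL-membrane serial barrier system.

The apparent permeability of a stirred diffusion cell combines two
resistances in series: the unstirred water layer (UWL) adjacent to the
membrane and the membrane itself,

    1/P_app = 1/P_UWL + 1/P_membrane.

For an ionizable, complexable drug the membrane term scales with the
neutral fraction f_0 and the unbound fraction f_u,

    P_membrane = f_u * f_0 * P_membrane_u0,

where P_membrane_u0 is the intrinsic permeability of the neutral, unbound
species. The Gutknecht method fits a measured P_app-pH profile to this
model and decomposes it into P_membrane_u0 and a pH-independent P_UWL.
Aqueous diffusivity follows an empirical molecular-weight power law and
converts P_UWL into a UWL thickness h = D/P.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .speciation import IonizationClass, neutral_fraction

#: Default coefficients (alpha in cm^2/s, beta dimensionless) of the
#: empirical aqueous-diffusivity power law D = alpha * MW**(-beta) at 37 C.
DEFAULT_DIFFUSIVITY_COEFFICIENTS: tuple[float, float] = (9.9e-5, 0.453)

#: The UWL permeability is reported as unidentifiable when its fitted
#: value exceeds this multiple of the largest observed P_app (its
#: resistance is then invisible against the membrane term).
_UWL_UNBOUNDED_FACTOR = 1.0e3


@dataclass(frozen=True)
class UWLModel:
    """Unstirred water layer described by diffusivity, thickness, permeability."""

    D_UWL: float
    h_UWL: float

    def __post_init__(self) -> None:
        if self.D_UWL <= 0 or self.h_UWL <= 0:
            raise ValueError("D_UWL and h_UWL must be positive")

    @property
    def P_UWL(self) -> float:
        return self.D_UWL / self.h_UWL


@dataclass(frozen=True)
class PermeabilityDecomposition:
    """Serial decomposition of one experimental condition (all cm/s)."""

    P_UWL: float
    P_membrane_u0: float
    f_0: float = 1.0
    f_u: float = 1.0

    def __post_init__(self) -> None:
        if self.P_UWL <= 0 or self.P_membrane_u0 <= 0:
            raise ValueError("permeabilities must be positive")
        for name in ("f_0", "f_u"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def P_membrane(self) -> float:
        return membrane_permeability_with_cd(self.P_membrane_u0, self.f_0, self.f_u)

    @property
    def P_app(self) -> float:
        return serial_permeability(self.P_UWL, self.P_membrane)


@dataclass(frozen=True)
class PermeabilityPHProfile:
    """Apparent-permeability observations over pH at one stirring rate."""

    pH: tuple[float, ...]
    P_app: tuple[float, ...]
    stirring_rpm: float = 250.0
    sd: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        ph = tuple(float(x) for x in self.pH)
        p = tuple(float(x) for x in self.P_app)
        object.__setattr__(self, "pH", ph)
        object.__setattr__(self, "P_app", p)
        if len(ph) != len(p):
            raise ValueError("pH and P_app must have equal length")
        if len(set(ph)) != len(ph):
            raise ValueError("pH values must be distinct within a stirring group")
        if any(x <= 0 for x in p):
            raise ValueError("P_app values must be positive")


@dataclass(frozen=True)
class GutknechtFit:
    """Result of a Gutknecht pH-profile decomposition."""

    P_membrane_u0: float
    P_UWL: float
    residual_norm: float
    uwl_identifiable: bool = True
    fitted_P_app: tuple[float, ...] = field(default_factory=tuple)


def apparent_permeability(flux: float, donor_concentration: float) -> float:
    """P_app = J / c_donor.

    ``flux`` in ug cm^-2 s^-1 and ``donor_concentration`` in ug/mL give
    cm/s directly (1 mL = 1 cm^3).
    """
    if donor_concentration <= 0:
        raise ValueError("donor concentration must be positive")
    return flux / donor_concentration


def serial_permeability(P_UWL: float, P_membrane: float) -> float:
    """Harmonic composition 1/P_app = 1/P_UWL + 1/P_membrane."""
    if P_UWL <= 0 or P_membrane <= 0:
        raise ValueError("permeabilities must be positive")
    return 1.0 / (1.0 / P_UWL + 1.0 / P_membrane)


def membrane_permeability_with_cd(P_membrane_u0: float, f_0: float, f_u: float) -> float:
    """Membrane permeability of the total drug: P_m = f_u * f_0 * P_m_u0."""
    if not 0.0 <= f_0 <= 1.0 or not 0.0 <= f_u <= 1.0:
        raise ValueError("fractions must lie in [0, 1]")
    return f_u * f_0 * P_membrane_u0


def gutknecht_fit(
    profile: PermeabilityPHProfile,
    pKa: float,
    ionization_class: IonizationClass | str = IonizationClass.MONOPROTIC_BASE,
) -> GutknechtFit:
    """Decompose a P_app-pH profile into P_membrane_u0 and P_UWL.

    Fits, by bounded nonlinear least squares in reciprocal-permeability
    space (unweighted),

        1/P_app(pH) = 1/P_UWL + 1/(f_0(pH) * P_membrane_u0).

    Initialization: P_UWL at the largest observed P_app, P_membrane_u0
    from the lowest-pH point divided by its f_0 (the membrane-limited
    end of the profile). If the fitted P_UWL runs to the upper bound the
    profile carries no UWL information (all points membrane-limited) and
    ``uwl_identifiable`` is False with P_UWL reported as infinity.
    """
    ph = np.asarray(profile.pH, dtype=float)
    p_app = np.asarray(profile.P_app, dtype=float)
    if len(ph) < 3:
        raise ValueError("need at least 3 pH points")
    ion = IonizationClass(ionization_class)
    f0 = np.array([neutral_fraction(pKa, x, ion) for x in ph])

    # order by increasing f_0 so [0] is the most membrane-limited point
    most_ionized = int(np.argmin(f0))
    p0_init = p_app[most_ionized] / f0[most_ionized]
    puwl_init = float(np.max(p_app)) * 1.5

    def residuals(theta: np.ndarray) -> np.ndarray:
        p0, puwl = theta
        return 1.0 / p_app - (1.0 / puwl + 1.0 / (f0 * p0))

    fit = least_squares(
        residuals,
        x0=[p0_init, puwl_init],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    p0, puwl = (float(v) for v in fit.x)
    identifiable = puwl < _UWL_UNBOUNDED_FACTOR * float(np.max(p_app))
    fitted = tuple(serial_permeability(puwl, f * p0) for f in f0)
    return GutknechtFit(
        P_membrane_u0=p0,
        P_UWL=puwl if identifiable else float("inf"),
        residual_norm=float(np.linalg.norm(fit.fun)),
        uwl_identifiable=identifiable,
        fitted_P_app=fitted,
    )


def aqueous_diffusivity(
    molecular_weight: float,
    coefficients: tuple[float, float] = DEFAULT_DIFFUSIVITY_COEFFICIENTS,
) -> float:
    """Aqueous diffusion coefficient at 37 C from the MW power law.

    ``D = alpha * MW**(-beta)`` in cm^2/s, with configurable empirical
    coefficients (default alpha = 9.9e-5 cm^2/s, beta = 0.453).
    """
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    alpha, beta = coefficients
    return alpha * molecular_weight ** (-beta)


def apparent_diffusivity_with_cd(f_u: float, D_mono: float, D_complex: float) -> float:
    """Speciation-weighted aqueous diffusivity of the drug with ligand present.

    ``D_app = f_u * D_mono + (1 - f_u) * D_complex`` -- the free monomer
    and the drug-ligand complex diffuse in parallel with fractions f_u
    and 1-f_u of the total drug.
    """
    if not 0.0 <= f_u <= 1.0:
        raise ValueError("f_u must lie in [0, 1]")
    return f_u * D_mono + (1.0 - f_u) * D_complex


def uwl_thickness(P_UWL: float, D: float) -> float:
    """UWL thickness h = D / P_UWL (cm), the film-model identity."""
    if P_UWL <= 0 or D <= 0:
        raise ValueError("inputs must be positive")
    return D / P_UWL
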