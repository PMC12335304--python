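"""Unit conversions used throughout the package.

Internal conventions:

* equilibrium constants and binding math are in molar units (K has units
  1/M, so concentrations entering :mod:`ssrflux.speciation` are mol/L);
* permeabilities are cm/s at the API surface, converted to cm/min inside
  the simulator (experiment clocks run in minutes);
* mass concentrations are ug/mL (== ug/cm^3, since 1 mL = 1 cm^3);
* fluxes are ug cm^-2 min^-1 unless a function says otherwise.

All conversions live here so there is exactly one table to test.
"""

from __future__ import annotations

SECONDS_PER_MINUTE = 60.0
ML_PER_CM3 = 1.0  # 1 mL == 1 cm^3; recorded for readability


def mass_conc_to_molar(c_ug_per_ml: float, molecular_weight: float) -> float:
    """Convert ug/mL to mol/L. ``molecular_weight`` in g/mol."""
    if molecular_weight <= 0:
        raise ValueError("molecular_weight must be positive")
    # ug/mL = mg/L; mg/L / (g/mol) = mmol/L * 1e-3 = mol/L * 1e-3
    return c_ug_per_ml * 1e-3 / molecular_weight


def molar_to_mass_conc(c_molar: float, molecular_weight: float) -> float:
    """Convert mol/L to ug/mL. ``molecular_weight`` in g/mol."""
    if molecular_weight <= 0:
        raise ValueError("molecular_weight must be positive")
    return c_molar * molecular_weight * 1e3


def cm_per_s_to_cm_per_min(p: float) -> float:
    return p * SECONDS_PER_MINUTE


def cm_per_min_to_cm_per_s(p: float) -> float:
    return p / SECONDS_PER_MINUTE


def flux_per_s_to_per_min(j: float) -> float:
    """ug cm^-2 s^-1 -> ug cm^-2 min^-1."""
    return j * SECONDS_PER_MINUTE


def flux_per_min_to_per_s(j: float) -> float:
    """ug cm^-2 min^-1 -> ug cm^-2 s^-1."""
    return j / SECONDS_PER_MINUTE
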