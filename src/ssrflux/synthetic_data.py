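"""Synthetic diffusion-cell experiments with known ground truth.

Generates every input the analysis pipeline consumes — phase-solubility
datasets, apparent-permeability pH profiles, and full donor/acceptor
time courses — from the forward models in this package, so each stage
can be tested against the parameters that generated its data.

The default constants emulate a uFLUX-style side-by-side cell study of
carvedilol (a monoprotic weak base, MW 406.482, pKa 7.78) with
hydroxypropyl-beta-cyclodextrin (MW 1391) as solubilizer: 18-20 mL
stirred compartments, a 1.54 cm^2 membrane, pH 10 buffer, 37 C, a dose
ladder of a few ug/mL to tens of ug/mL, 15 mg/mL ligand in the donor,
and UV-probe-like sampling every few minutes for 8 h. Measurement noise
is multiplicative lognormal (relative error of a UV probe; default sd
2 %), appropriate for concentrations spanning orders of magnitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import units
from .barriers import aqueous_diffusivity, serial_permeability, PermeabilityPHProfile
from .speciation import (
    CompoundSpec,
    IonizationClass,
    LigandSpec,
    PhaseSolubilityDataset,
    neutral_fraction,
    phase_solubility_line,
)
from .transport_sim import (
    CellSimulationResult,
    DiffusionCellConfig,
    MembraneBarrier,
    MembraneKind,
    SimulationOptions,
    TransportCoefficients,
    b_uwl_coefficient,
    simulate_cell,
)

# ---------------------------------------------------------------------------
# default registry: the study compounds and cell geometry

CARVEDILOL = CompoundSpec(
    name="carvedilol",
    molecular_weight=406.482,
    ionization_class=IonizationClass.MONOPROTIC_BASE,
    pKa=7.78,
    solubility_by_medium={
        "pH10_buffer_form1": 2.15,
        "pH10_buffer_cd15_form1": 6.69,
        "pH10_buffer_form2": 3.37,
        "pH10_buffer_cd15_form2": 10.64,
    },
)

HPBCD = LigandSpec(name="HP-beta-CD", molecular_weight=1391.0)

#: Stability constants (1/M) of the 1:1 complex for the two polymorph-
#: conditioned solution states.
K_FORM1 = 178.4
K_FORM2 = 254.1

#: Intrinsic membrane permeability of the neutral, unbound drug through
#: the alkane-impregnated lipophilic membrane, cm/s.
P_MEMBRANE_U0_LIPOPHILIC = 2.89e-4

#: Aqueous membrane permeability used for size-exclusion membranes, cm/s
#: (water-filled pores; no pH dependence).
P_MEMBRANE_SIZE_EXCLUSION = 4.0e-5

#: Stirring-rate -> UWL thickness map (cm). Unstirred planar cells carry
#: films of a few mm; vigorous stirring thins them toward a few hundred um.
DEFAULT_H_UWL_BY_RPM: dict[float, float] = {
    0.0: 0.30,
    25.0: 0.12,
    50.0: 0.09,
    100.0: 0.06,
    250.0: 0.035,
    400.0: 0.028,
    600.0: 0.022,
}

#: Donor ligand level used across the study arms, ug/mL (15 mg/mL).
DEFAULT_LIGAND_DONOR_UG_ML = 15_000.0

DEFAULT_SAMPLING_TIMES = tuple(float(t) for t in range(0, 481, 5))


def calibrate_ligand_permeability(
    endpoint_concentration: float,
    elapsed_min: float,
    donor_concentration: float = DEFAULT_LIGAND_DONOR_UG_ML,
    V_donor: float = 20.0,
    V_acceptor: float = 20.0,
    area: float = 1.54,
) -> float:
    """Ligand permeability (cm/s) matching an observed acceptor endpoint.

    Inverts the two-compartment exponential for a solute crossing at
    first order: the acceptor concentration after ``elapsed_min`` minutes
    equals ``c_D0 * V_D/(V_D+V_A) * (1 - exp(-k t))`` with
    ``k = P * A * (1/V_D + 1/V_A)``.
    """
    c_inf = donor_concentration * V_donor / (V_donor + V_acceptor)
    frac = endpoint_concentration / c_inf
    if not 0.0 < frac < 1.0:
        raise ValueError("endpoint must lie strictly between 0 and the mixed limit")
    k = -np.log(1.0 - frac) / elapsed_min
    p_cm_min = k / (area * (1.0 / V_donor + 1.0 / V_acceptor))
    return units.cm_per_min_to_cm_per_s(p_cm_min)


#: Ligand permeabilities (cm/s) calibrated so the acceptor reaches the
#: observed 8-h endpoints (516 and 377 ug/mL from a 15 mg/mL donor).
LIGAND_PERMEABILITY_6KDA = calibrate_ligand_permeability(516.0, 480.0)
LIGAND_PERMEABILITY_1KDA = calibrate_ligand_permeability(377.0, 480.0)


def default_membrane(kind: str, stirring_rpm: float = 250.0) -> MembraneBarrier:
    """Study membranes: 'lipophilic', '6kDa', or '1kDa'."""
    if kind == "lipophilic":
        return MembraneBarrier(kind=MembraneKind.LIPOPHILIC, area=1.54)
    if kind == "6kDa":
        return MembraneBarrier(
            kind=MembraneKind.SIZE_EXCLUSION,
            area=1.54,
            MWCO_kDa=6.0,
            ligand_permeability=LIGAND_PERMEABILITY_6KDA,
        )
    if kind == "1kDa":
        return MembraneBarrier(
            kind=MembraneKind.SIZE_EXCLUSION,
            area=1.54,
            MWCO_kDa=1.0,
            ligand_permeability=LIGAND_PERMEABILITY_1KDA,
        )
    raise ValueError(f"unknown membrane kind {kind!r}")


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulated experimental arm with its ground truth.

    ``dose_ladder`` is in ug/mL of drug in the donor; ``ligand_donor``
    in ug/mL (0 for the plain-buffer arm). ``noise_sd`` is the relative
    standard deviation of the multiplicative lognormal measurement
    noise. A fixed seed makes the output byte-identical.
    """

    drug: CompoundSpec = CARVEDILOL
    ligand: LigandSpec = HPBCD
    K_1to1: float = K_FORM1
    membrane_kind: str = "lipophilic"
    stirring_rpm: float = 250.0
    pH: float = 10.0
    dose_ladder: tuple[float, ...] = (2.5, 5.0, 10.0, 15.0, 20.0)
    ligand_donor: float = 0.0
    solubility_buffer: float = 2.15
    V_donor: float = 18.0
    V_acceptor: float = 18.0
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING_TIMES
    h_UWL_by_rpm: tuple[tuple[float, float], ...] = tuple(
        DEFAULT_H_UWL_BY_RPM.items()
    )
    noise_sd: float = 0.02
    replicates: int = 1
    seed: int = 0
    precipitation: bool = False
    precipitation_onset_min: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def h_UWL(self) -> float:
        mapping = dict(self.h_UWL_by_rpm)
        if self.stirring_rpm not in mapping:
            raise KeyError(f"no UWL thickness configured for {self.stirring_rpm} rpm")
        return mapping[self.stirring_rpm]

    def membrane(self) -> MembraneBarrier:
        return default_membrane(self.membrane_kind, self.stirring_rpm)


def scenario_coefficients(spec: ScenarioSpec) -> TransportCoefficients:
    """B coefficients of a scenario from its physical parameters.

    ``B_UWL = D_mono * S_buffer / h_UWL`` and ``B_m = P_m * S_buffer``
    with the membrane permeability of the total drug at the scenario pH
    (``f_0 * P_m_u0`` for the lipophilic membrane; the pH-independent
    aqueous pore permeability for size exclusion). The same coefficients
    apply to the ligand-containing arm: in the SSR formulation the
    solubilization of the donor enters through the SSR denominator, not
    through B_e.
    """
    d_mono = aqueous_diffusivity(spec.drug.molecular_weight)
    b_uwl = b_uwl_coefficient(d_mono, spec.solubility_buffer, spec.h_UWL, per="min")
    if spec.membrane_kind == "lipophilic":
        f0 = neutral_fraction(spec.drug.pKa, spec.pH, spec.drug.ionization_class)
        p_m = P_MEMBRANE_U0_LIPOPHILIC * f0
    else:
        p_m = P_MEMBRANE_SIZE_EXCLUSION
    b_m = units.cm_per_s_to_cm_per_min(p_m) * spec.solubility_buffer
    return TransportCoefficients(
        B_UWL=b_uwl,
        B_m=b_m,
        C_star_UWL=spec.solubility_buffer,
        C_star_D=spec.solubility_buffer,
        C_star_A=spec.solubility_buffer,
        D_UWL_eff=d_mono,
        h_UWL_eff=spec.h_UWL,
    )


def make_phase_solubility(
    S_0: float,
    K_1to1: float,
    ligand_levels: tuple[float, ...] | np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PhaseSolubilityDataset:
    """A_L-type phase-solubility dataset (molar axes) with known truth.

    Solubility follows the exact 1:1 line
    ``S(L) = S_0 * (1 + K*L / (1 + K*S_0))``, perturbed multiplicatively
    by lognormal noise of relative sd ``noise_sd``.
    """
    if S_0 <= 0 or K_1to1 < 0:
        raise ValueError("S_0 must be positive and K non-negative")
    lig = np.asarray(ligand_levels, dtype=float)
    s = phase_solubility_line(S_0, K_1to1, lig)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        s = s * np.exp(rng.normal(0.0, noise_sd, size=s.shape))
    return PhaseSolubilityDataset(
        ligand_concentrations=tuple(lig), measured_solubilities=tuple(s)
    )


def make_ph_profile(
    P_membrane_u0: float,
    P_UWL: float,
    pH_grid: tuple[float, ...] | np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    pKa: float = 7.78,
    ionization_class: IonizationClass | str = IonizationClass.MONOPROTIC_BASE,
    stirring_rpm: float = 250.0,
) -> PermeabilityPHProfile:
    """Apparent-permeability pH profile generated from the serial model.

    ``P_app(pH) = 1 / (1/P_UWL + 1/(f_0(pH) * P_membrane_u0))`` with
    multiplicative lognormal noise of relative sd ``noise_sd``.
    """
    ph = np.asarray(pH_grid, dtype=float)
    if ph.size == 0:
        raise ValueError("pH grid must be non-empty")
    p_app = np.array(
        [
            serial_permeability(
                P_UWL, neutral_fraction(pKa, x, ionization_class) * P_membrane_u0
            )
            for x in ph
        ]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        p_app = p_app * np.exp(rng.normal(0.0, noise_sd, size=p_app.shape))
    return PermeabilityPHProfile(pH=tuple(ph), P_app=tuple(p_app), stirring_rpm=stirring_rpm)


@dataclass(frozen=True)
class CellExperiment:
    """One simulated run with its observation-noise overlay."""

    dose: float
    replicate: int
    truth: CellSimulationResult
    observed: CellSimulationResult


def _add_observation_noise(
    result: CellSimulationResult, noise_sd: float, rng: np.random.Generator
) -> CellSimulationResult:
    if noise_sd <= 0:
        return result
    donor = result.donor_total * np.exp(
        rng.normal(0.0, noise_sd, size=result.donor_total.shape)
    )
    acceptor = result.acceptor_total * np.exp(
        rng.normal(0.0, noise_sd, size=result.acceptor_total.shape)
    )
    return replace(
        result,
        donor_total=donor,
        acceptor_total=acceptor,
        SSR_donor=donor / result.solubility_donor_eff,
        SSR_acceptor=acceptor / result.solubility_acceptor_eff,
    )


def make_cell_experiment(spec: ScenarioSpec) -> list[CellExperiment]:
    """Simulate the scenario's dose ladder with replicates and noise.

    Each dose/replicate pair is forward-simulated (the noiseless truth)
    and then overlaid with multiplicative measurement noise on the
    donor/acceptor concentration channels, as a UV probe would see them.
    The RNG stream is a single ``default_rng(seed)`` consumed in
    dose-major, replicate-minor order.
    """
    rng = np.random.default_rng(spec.seed)
    membrane = spec.membrane()
    coeffs = scenario_coefficients(spec)
    lig_molar = (
        units.mass_conc_to_molar(spec.ligand_donor, spec.ligand.molecular_weight)
        if spec.ligand_donor > 0
        else 0.0
    )
    options = SimulationOptions(
        precipitation=spec.precipitation,
        precipitation_onset_min=spec.precipitation_onset_min,
    )
    out: list[CellExperiment] = []
    for dose in spec.dose_ladder:
        config = DiffusionCellConfig(
            V_donor=spec.V_donor,
            V_acceptor=spec.V_acceptor,
            membrane=membrane,
            drug_dose_donor=dose,
            solubility_donor=spec.solubility_buffer,
            solubility_acceptor=spec.solubility_buffer,
            sampling_times=spec.sampling_times,
            ligand_total_donor=lig_molar,
            stirring_rpm=spec.stirring_rpm,
            pH=spec.pH,
            seed=spec.seed,
        )
        truth = simulate_cell(
            config,
            spec.drug,
            spec.ligand if lig_molar > 0 else None,
            spec.K_1to1 if lig_molar > 0 else 0.0,
            coefficients=coeffs,
            options=options,
        )
        for rep in range(spec.replicates):
            observed = _add_observation_noise(truth, spec.noise_sd, rng)
            out.append(CellExperiment(dose=dose, replicate=rep, truth=truth, observed=observed))
    return out


def write_scenario_fixtures(spec: ScenarioSpec, outdir: str | Path) -> Path:
    """Write `truth.json`, `timeseries.csv`, `phase_solubility.csv`.

    The truth metadata records every generating parameter, so pipeline
    targets can be recomputed without re-reading generator internals.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    experiments = make_cell_experiment(spec)
    coeffs = scenario_coefficients(spec)

    frames = []
    for exp in experiments:
        frame = exp.observed.to_tidy_frame()
        frame.insert(0, "dose_ug_ml", exp.dose)
        frame.insert(1, "replicate", exp.replicate)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "timeseries.csv", index=False, float_format="%.17g"
    )

    s0_molar = units.mass_conc_to_molar(spec.solubility_buffer, spec.drug.molecular_weight)
    ligand_levels_ug_ml = (0.0, 2500.0, 5000.0, 10000.0, 15000.0, 20000.0)
    ps = make_phase_solubility(
        s0_molar,
        spec.K_1to1,
        tuple(
            units.mass_conc_to_molar(v, spec.ligand.molecular_weight)
            for v in ligand_levels_ug_ml
        ),
        noise_sd=spec.noise_sd,
        seed=spec.seed + 1,
    )
    pd.DataFrame(
        {
            "ligand_conc": ps.ligand_concentrations,
            "solubility": ps.measured_solubilities,
        }
    ).to_csv(outdir / "phase_solubility.csv", index=False, float_format="%.17g")

    truth = {
        "drug": {
            "name": spec.drug.name,
            "molecular_weight": spec.drug.molecular_weight,
            "pKa": spec.drug.pKa,
            "ionization_class": spec.drug.ionization_class.value,
        },
        "ligand": {
            "name": spec.ligand.name,
            "molecular_weight": spec.ligand.molecular_weight,
        },
        "K_1to1_per_M": spec.K_1to1,
        "membrane_kind": spec.membrane_kind,
        "ligand_permeability_cm_s": spec.membrane().ligand_permeability,
        "stirring_rpm": spec.stirring_rpm,
        "pH": spec.pH,
        "h_UWL_cm": spec.h_UWL,
        "solubility_buffer_ug_ml": spec.solubility_buffer,
        "ligand_donor_ug_ml": spec.ligand_donor,
        "dose_ladder_ug_ml": list(spec.dose_ladder),
        "B_UWL": coeffs.B_UWL,
        "B_m": coeffs.B_m,
        "B_e": coeffs.B_e,
        "noise_sd": spec.noise_sd,
        "replicates": spec.replicates,
        "seed": spec.seed,
        "units": {
            "concentration": "ug/mL",
            "time": "min",
            "B": "ug cm^-2 min^-1 per unit SSR",
            "phase_solubility": "mol/L",
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return outdir
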