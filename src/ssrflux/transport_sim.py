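"""Two-compartment diffusion-cell simulator with SSR-driven flux.

The forward model treats a stirred donor and acceptor compartment
separated by a membrane of area ``A``. Drug flux across the serial
UWL-membrane barrier is proportional to the difference in
supersaturation ratio (SSR) between the compartments,

    J = B_e * (SSR_donor - SSR_acceptor),      SSR = c / S(medium),

where ``B_e`` combines the UWL and membrane proportionality coefficients
reciprocally, ``1/B_e = 1/B_UWL + 1/B_m``, and each ``B = D * C* / h``
(diffusivity times saturation concentration over film thickness). The
SSR form makes the driving force invariant to solubilization: adding a
complexing ligand to the donor raises the solubility and lowers the free
fraction in exact proportion, leaving flux-vs-dSSR lines parallel as
long as neither ligand nor complex crosses the membrane.

Size-exclusion (dialysis) membranes break that assumption: the ligand
leaks with a first-order two-compartment law at its own permeability,
raising the acceptor solubility as it arrives, and the drug-ligand
complex carries additional drug flux. Both effects are modelled here.

Speciation (1:1 binding) is re-solved algebraically at every integrator
step (quasi-equilibrium; no binding kinetics). Optional donor
precipitation is an instantaneous clamp of the dissolved concentration
at the local, ligand-dependent solubility, with the excess held as a
redissolvable precipitated mass.

Internal units: mass ug, volume mL, time min, area cm^2, concentration
ug/mL; permeabilities are accepted in cm/s and converted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import units
from .barriers import PermeabilityDecomposition
from .speciation import CompoundSpec, LigandSpec, solve_binding_equilibrium

_MASS_BALANCE_RTOL = 1e-8
_NEGATIVE_GUARD = -1e-9


class MembraneKind(str, enum.Enum):
    LIPOPHILIC = "lipophilic"
    SIZE_EXCLUSION = "size_exclusion"


@dataclass(frozen=True)
class TransportCoefficients:
    """SSR flux-model coefficients, ug cm^-2 min^-1 per unit SSR.

    ``B_UWL`` and ``B_m`` are the UWL and membrane proportionality
    coefficients; ``B_e`` is their reciprocal (serial) combination. The
    optional film parameters record how ``B_UWL`` was built
    (``B_UWL = D_UWL_eff * C_star_UWL / h_UWL_eff``) and the steady-state
    partition ratios K_d1 = C*_UWL/C*_D, K_d2 = C*_UWL/C*_A.
    """

    B_UWL: float
    B_m: float
    C_star_UWL: float | None = None
    C_star_D: float | None = None
    C_star_A: float | None = None
    D_UWL_eff: float | None = None
    h_UWL_eff: float | None = None

    def __post_init__(self) -> None:
        if self.B_UWL <= 0 or self.B_m <= 0:
            raise ValueError("B coefficients must be positive")

    @property
    def B_e(self) -> float:
        return b_effective(self.B_UWL, self.B_m)

    @property
    def K_d1(self) -> float | None:
        if self.C_star_UWL is None or self.C_star_D is None:
            return None
        return self.C_star_UWL / self.C_star_D

    @property
    def K_d2(self) -> float | None:
        if self.C_star_UWL is None or self.C_star_A is None:
            return None
        return self.C_star_UWL / self.C_star_A


@dataclass(frozen=True)
class MembraneBarrier:
    """Membrane separating the compartments.

    ``ligand_permeability`` (cm/s) is the first-order two-compartment
    permeability of the free ligand; it must be 0 for a lipophilic
    membrane. ``complex_permeability`` defaults to the ligand value (the
    drug-ligand complex is of comparable hydrodynamic size).
    """

    kind: MembraneKind
    area: float = 1.54
    MWCO_kDa: float | None = None
    ligand_permeability: float = 0.0
    complex_permeability: float | None = None
    thickness: float | None = None
    D_m: float | None = None
    C_star_m: float | None = None

    def __post_init__(self) -> None:
        kind = MembraneKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if self.area <= 0:
            raise ValueError("membrane area must be positive")
        if self.ligand_permeability < 0:
            raise ValueError("ligand_permeability must be non-negative")
        if kind is MembraneKind.LIPOPHILIC and self.ligand_permeability != 0.0:
            raise ValueError("a lipophilic membrane passes no ligand")

    @property
    def effective_complex_permeability(self) -> float:
        if self.kind is MembraneKind.LIPOPHILIC:
            return 0.0
        if self.complex_permeability is None:
            return self.ligand_permeability
        return self.complex_permeability


@dataclass(frozen=True)
class WithdrawalEvent:
    """Discrete sampling withdrawal: remove ``volume_ml`` of fluid."""

    time_min: float
    volume_ml: float
    compartments: tuple[str, ...] = ("donor", "acceptor")


@dataclass(frozen=True)
class SimulationOptions:
    """Switches for the optional physics.

    ``precipitation`` enables the donor solubility clamp;
    ``precipitation_onset_min`` delays it (a metastable supersaturated
    window before nucleation). ``withdrawals`` removes fluid at the
    configured times (concentrations unchanged, masses and volume
    reduced).
    """

    precipitation: bool = False
    precipitation_onset_min: float = 0.0
    withdrawals: tuple[WithdrawalEvent, ...] = ()
    rtol: float = 1e-10
    atol: float = 1e-12


@dataclass(frozen=True)
class DiffusionCellConfig:
    """Geometry, media and dosing of one side-by-side diffusion cell run.

    ``solubility_donor`` / ``solubility_acceptor`` are the ligand-free
    (buffer) solubilities of each side's medium in ug/mL; the simulator
    raises each side's effective solubility linearly with the local
    ligand concentration using the phase-solubility slope implied by the
    stability constant. ``ligand_total_donor`` is molar.
    """

    V_donor: float
    V_acceptor: float
    membrane: MembraneBarrier
    drug_dose_donor: float
    solubility_donor: float
    solubility_acceptor: float
    sampling_times: tuple[float, ...]
    ligand_total_donor: float = 0.0
    stirring_rpm: float = 250.0
    pH: float = 10.0
    temperature: float = 37.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.V_donor <= 0 or self.V_acceptor <= 0:
            raise ValueError("volumes must be positive")
        if self.solubility_donor <= 0 or self.solubility_acceptor <= 0:
            raise ValueError("solubilities must be positive")
        t = tuple(float(x) for x in self.sampling_times)
        object.__setattr__(self, "sampling_times", t)
        if len(t) < 2 or t[0] != 0.0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("sampling times must strictly increase from 0")


@dataclass(frozen=True)
class CellSimulationResult:
    """Time series of one simulated run (concentrations ug/mL, mass ug)."""

    times: np.ndarray
    donor_total: np.ndarray
    acceptor_total: np.ndarray
    donor_free: np.ndarray
    donor_complexed: np.ndarray
    acceptor_free: np.ndarray
    acceptor_complexed: np.ndarray
    ligand_donor: np.ndarray
    ligand_acceptor: np.ndarray
    precipitated_mass: np.ndarray
    SSR_donor: np.ndarray
    SSR_acceptor: np.ndarray
    solubility_donor_eff: np.ndarray
    solubility_acceptor_eff: np.ndarray
    V_donor: np.ndarray
    V_acceptor: np.ndarray
    withdrawn_drug: float = 0.0
    withdrawn_ligand: float = 0.0
    metadata: dict = field(default_factory=dict)

    def total_drug_mass(self) -> np.ndarray:
        """Drug mass in the system at each sample (excludes withdrawn)."""
        return (
            self.donor_total * self.V_donor
            + self.acceptor_total * self.V_acceptor
            + self.precipitated_mass
        )

    def total_ligand_mass(self) -> np.ndarray:
        return self.ligand_donor * self.V_donor + self.ligand_acceptor * self.V_acceptor

    def to_tidy_frame(self):
        """Long-format frame: time_min, compartment, species, concentration."""
        import pandas as pd

        blocks = []
        series = {
            ("donor", "drug_total"): self.donor_total,
            ("donor", "drug_free"): self.donor_free,
            ("donor", "drug_complexed"): self.donor_complexed,
            ("donor", "ligand"): self.ligand_donor,
            ("acceptor", "drug_total"): self.acceptor_total,
            ("acceptor", "drug_free"): self.acceptor_free,
            ("acceptor", "drug_complexed"): self.acceptor_complexed,
            ("acceptor", "ligand"): self.ligand_acceptor,
        }
        for (comp, spec), values in series.items():
            blocks.append(
                pd.DataFrame(
                    {
                        "time_min": self.times,
                        "compartment": comp,
                        "species": spec,
                        "concentration": values,
                    }
                )
            )
        return pd.concat(blocks, ignore_index=True)


def ssr(concentration: float, solubility_same_medium: float) -> float:
    """Supersaturation ratio: dissolved concentration over the solubility
    measured in exactly the same medium. SSR > 1 flags supersaturation."""
    if solubility_same_medium <= 0:
        raise ValueError("solubility must be positive")
    return concentration / solubility_same_medium


def b_uwl_coefficient(
    D_UWL_eff: float, C_star_UWL: float, h_UWL_eff: float, per: str = "s"
) -> float:
    """UWL proportionality coefficient B_UWL = D * C* / h.

    With D in cm^2/s, C* in ug/mL and h in cm the result is in
    ug cm^-2 s^-1 per unit SSR (``per="min"`` converts to minutes).
    """
    if D_UWL_eff <= 0 or C_star_UWL <= 0 or h_UWL_eff <= 0:
        raise ValueError("inputs must be positive")
    b = D_UWL_eff * C_star_UWL / h_UWL_eff
    if per == "min":
        return units.flux_per_s_to_per_min(b)
    if per != "s":
        raise ValueError("per must be 's' or 'min'")
    return b


def b_effective(B_UWL: float, B_m: float) -> float:
    """Serial combination 1/B_e = 1/B_UWL + 1/B_m."""
    if B_UWL <= 0 or B_m <= 0:
        raise ValueError("B coefficients must be positive")
    return 1.0 / (1.0 / B_UWL + 1.0 / B_m)


def flux_general_model(B_e: float, SSR_donor: float, SSR_acceptor: float) -> float:
    """General flux model J = B_e * (SSR_donor - SSR_acceptor)."""
    if B_e <= 0:
        raise ValueError("B_e must be positive")
    return B_e * (SSR_donor - SSR_acceptor)


def coefficients_from_permeability(
    decomposition: PermeabilityDecomposition, C_star: float
) -> TransportCoefficients:
    """Convert a P-form barrier description into B coefficients.

    ``B = P * C*`` for each barrier, with P converted from cm/s to
    cm/min and ``C_star`` the donor-medium saturation concentration in
    ug/mL, so that in the linear (shared-medium) regime
    ``J = B_e * dSSR`` reduces exactly to ``J = P_app * (c_D - c_A)``.
    """
    if C_star <= 0:
        raise ValueError("C_star must be positive")
    p_uwl = units.cm_per_s_to_cm_per_min(decomposition.P_UWL)
    p_m = units.cm_per_s_to_cm_per_min(decomposition.P_membrane)
    return TransportCoefficients(
        B_UWL=p_uwl * C_star, B_m=p_m * C_star, C_star_UWL=C_star
    )


class _CellModel:
    """ODE right-hand side over state [m_D, m_A, m_prec, mL_D, mL_A] (ug)."""

    def __init__(
        self,
        config: DiffusionCellConfig,
        drug: CompoundSpec,
        ligand: LigandSpec | None,
        K_1to1: float,
        B_e: float,
    ) -> None:
        self.cfg = config
        self.drug = drug
        self.ligand = ligand
        self.K = float(K_1to1)
        self.B_e = B_e
        self.area = config.membrane.area
        self.P_L = units.cm_per_s_to_cm_per_min(config.membrane.ligand_permeability)
        self.P_cplx = units.cm_per_s_to_cm_per_min(
            config.membrane.effective_complex_permeability
        )
        # phase-solubility slope (dimensionless, molar) implied by K and
        # the donor buffer solubility; converts to a mass-basis slope.
        if ligand is not None and self.K > 0:
            s0_molar = units.mass_conc_to_molar(
                config.solubility_donor, drug.molecular_weight
            )
            slope_molar = self.K * s0_molar / (1.0 + self.K * s0_molar)
            self.slope_mass = slope_molar * drug.molecular_weight / ligand.molecular_weight
        else:
            self.slope_mass = 0.0
        self.V_D = config.V_donor
        self.V_A = config.V_acceptor

    def solubility_donor_eff(self, c_L_donor: float) -> float:
        return self.cfg.solubility_donor + self.slope_mass * c_L_donor

    def solubility_acceptor_eff(self, c_L_acceptor: float) -> float:
        return self.cfg.solubility_acceptor + self.slope_mass * c_L_acceptor

    def speciate(self, c_drug: float, c_ligand: float):
        """Free/complexed split (ug/mL of drug) at local totals."""
        if self.ligand is None or self.K == 0.0 or c_ligand <= 0.0:
            return c_drug, 0.0
        d_molar = units.mass_conc_to_molar(c_drug, self.drug.molecular_weight)
        l_molar = units.mass_conc_to_molar(c_ligand, self.ligand.molecular_weight)
        state = solve_binding_equilibrium(d_molar, l_molar, self.K)
        free = units.molar_to_mass_conc(state.free_drug, self.drug.molecular_weight)
        return free, c_drug - free

    def fluxes(self, y: np.ndarray) -> tuple[float, float]:
        """(drug flux, ligand flux) in ug cm^-2 min^-1, donor -> acceptor."""
        m_D, m_A, _, mL_D, mL_A = y
        c_D, c_A = m_D / self.V_D, m_A / self.V_A
        cL_D, cL_A = mL_D / self.V_D, mL_A / self.V_A
        s_D = self.solubility_donor_eff(cL_D)
        s_A = self.solubility_acceptor_eff(cL_A)
        j_drug = flux_general_model(self.B_e, ssr(c_D, s_D), ssr(c_A, s_A))
        if self.P_cplx > 0.0:
            _, cplx_D = self.speciate(c_D, cL_D)
            _, cplx_A = self.speciate(c_A, cL_A)
            j_drug += self.P_cplx * (cplx_D - cplx_A)
        j_ligand = self.P_L * (cL_D - cL_A)
        return j_drug, j_ligand

    def rhs_free(self, t: float, y: np.ndarray) -> np.ndarray:
        j_drug, j_ligand = self.fluxes(y)
        a = self.area
        return np.array([-a * j_drug, a * j_drug, 0.0, -a * j_ligand, a * j_ligand])

    def rhs_clamped(self, t: float, y: np.ndarray) -> np.ndarray:
        """Donor dissolved drug pinned at the local solubility.

        The dissolved pool tracks V_D * S_D(c_L); transport and the
        solubility drift are fed from / returned to the precipitate so
        total drug mass is conserved identically.
        """
        j_drug, j_ligand = self.fluxes(y)
        a = self.area
        d_mL_D = -a * j_ligand
        d_m_D = self.slope_mass * d_mL_D  # V_D * dS_D/dt
        return np.array(
            [d_m_D, a * j_drug, -a * j_drug - d_m_D, d_mL_D, a * j_ligand]
        )


def simulate_cell(
    config: DiffusionCellConfig,
    drug: CompoundSpec,
    ligand: LigandSpec | None = None,
    K_1to1: float = 0.0,
    coefficients: TransportCoefficients | PermeabilityDecomposition | None = None,
    options: SimulationOptions | None = None,
) -> CellSimulationResult:
    """Forward-integrate a side-by-side diffusion cell experiment.

    ``coefficients`` may be given in B-form (:class:`TransportCoefficients`)
    or P-form (:class:`PermeabilityDecomposition`, converted through the
    donor-medium saturation concentration at t = 0). Speciation is
    re-solved at every step; the ligand (and complex) cross the membrane
    only when the membrane's permeabilities allow it; precipitation, when
    enabled, clamps the donor dissolved concentration at the local
    effective solubility from ``options.precipitation_onset_min`` onward.
    """
    if coefficients is None:
        raise ValueError("transport coefficients are required")
    options = options or SimulationOptions()

    lig_conc0 = (
        units.molar_to_mass_conc(config.ligand_total_donor, ligand.molecular_weight)
        if ligand is not None and config.ligand_total_donor > 0
        else 0.0
    )
    model = _CellModel(config, drug, ligand, K_1to1, B_e=1.0)  # B_e set below
    if isinstance(coefficients, PermeabilityDecomposition):
        c_star = model.solubility_donor_eff(lig_conc0)
        coefficients = coefficients_from_permeability(coefficients, c_star)
    model.B_e = coefficients.B_e

    times = np.asarray(config.sampling_times, dtype=float)
    y = np.array(
        [
            config.drug_dose_donor * config.V_donor,
            0.0,
            0.0,
            lig_conc0 * config.V_donor,
            0.0,
        ]
    )
    total_drug0 = y[0] + y[1] + y[2]
    total_ligand0 = y[3] + y[4]
    withdrawn_drug = 0.0
    withdrawn_ligand = 0.0

    def apply_clamp(y: np.ndarray) -> np.ndarray:
        s_D = model.solubility_donor_eff(y[3] / model.V_D)
        cap = s_D * model.V_D
        if y[0] > cap:
            y = y.copy()
            y[2] += y[0] - cap
            y[0] = cap
        return y

    # breakpoints: withdrawals and the precipitation onset
    breaks: list[tuple[float, str]] = [(float(t), "sample") for t in times[1:]]
    if options.precipitation and options.precipitation_onset_min > 0.0:
        breaks.append((float(options.precipitation_onset_min), "onset"))
    for w in options.withdrawals:
        breaks.append((float(w.time_min), "withdraw"))
    breaks.sort(key=lambda item: item[0])

    clamp_active = False
    if options.precipitation and options.precipitation_onset_min <= 0.0:
        y = apply_clamp(y)
        clamp_active = y[2] > 0.0

    samples: dict[float, np.ndarray] = {0.0: y.copy()}
    volumes: dict[float, tuple[float, float]] = {0.0: (model.V_D, model.V_A)}
    withdrawn_at: dict[float, tuple[float, float]] = {0.0: (0.0, 0.0)}

    def integrate(y: np.ndarray, t0: float, t1: float, clamped: bool):
        """One segment; handles clamp engage/release events internally."""
        while t1 - t0 > 1e-12:
            rhs = model.rhs_clamped if clamped else model.rhs_free

            def release(t, yy):  # precipitate exhausted
                return yy[2]

            release.terminal = True
            release.direction = -1.0

            def engage(t, yy):  # dissolved crosses the (falling) solubility
                s_D = model.solubility_donor_eff(yy[3] / model.V_D)
                return yy[0] - s_D * model.V_D

            engage.terminal = True
            engage.direction = 1.0

            events = []
            if options.precipitation and t0 >= options.precipitation_onset_min - 1e-12:
                events = [release] if clamped else [engage]
            sol = solve_ivp(
                rhs,
                (t0, t1),
                y,
                method="DOP853",
                rtol=options.rtol,
                atol=options.atol,
                events=events or None,
                dense_output=False,
            )
            if not sol.success:
                raise RuntimeError(f"integration failed: {sol.message}")
            y = sol.y[:, -1].copy()
            t0 = float(sol.t[-1])
            if sol.status == 1:  # terminal event: flip regime
                clamped = not clamped
                if clamped:
                    y = apply_clamp(y)
                else:
                    y[2] = 0.0
        return y, clamped

    t_now = 0.0
    for t_next, kind in breaks:
        if t_next > t_now:
            y, clamp_active = integrate(y, t_now, t_next, clamp_active)
            t_now = t_next
        if kind == "onset":
            y = apply_clamp(y)
            clamp_active = y[2] > 0.0
        elif kind == "withdraw":
            event = next(
                w for w in options.withdrawals if abs(w.time_min - t_next) < 1e-12
            )
            if "donor" in event.compartments:
                frac = event.volume_ml / model.V_D
                if frac >= 1.0:
                    raise ValueError("withdrawal exceeds donor volume")
                withdrawn_drug += y[0] * frac
                withdrawn_ligand += y[3] * frac
                y[0] *= 1.0 - frac
                y[3] *= 1.0 - frac
                model.V_D -= event.volume_ml
            if "acceptor" in event.compartments:
                frac = event.volume_ml / model.V_A
                if frac >= 1.0:
                    raise ValueError("withdrawal exceeds acceptor volume")
                withdrawn_drug += y[1] * frac
                withdrawn_ligand += y[4] * frac
                y[1] *= 1.0 - frac
                y[4] *= 1.0 - frac
                model.V_A -= event.volume_ml
        if kind == "sample" or t_next in times:
            samples[t_next] = y.copy()
            volumes[t_next] = (model.V_D, model.V_A)
            withdrawn_at[t_next] = (withdrawn_drug, withdrawn_ligand)

    # assemble sampled series
    n = len(times)
    out = {
        name: np.zeros(n)
        for name in (
            "donor_total",
            "acceptor_total",
            "donor_free",
            "donor_complexed",
            "acceptor_free",
            "acceptor_complexed",
            "ligand_donor",
            "ligand_acceptor",
            "precipitated_mass",
            "SSR_donor",
            "SSR_acceptor",
            "solubility_donor_eff",
            "solubility_acceptor_eff",
            "V_donor",
            "V_acceptor",
        )
    }
    for i, t in enumerate(times):
        yi = samples[float(t)]
        v_d, v_a = volumes[float(t)]
        if np.any(yi < _NEGATIVE_GUARD * max(total_drug0, total_ligand0, 1.0)):
            raise RuntimeError(f"negative state at t={t}: {yi}")
        yi = np.maximum(yi, 0.0)
        c_D, c_A = yi[0] / v_d, yi[1] / v_a
        cL_D, cL_A = yi[3] / v_d, yi[4] / v_a
        s_D = model.solubility_donor_eff(cL_D)
        s_A = model.solubility_acceptor_eff(cL_A)
        free_D, cplx_D = model.speciate(c_D, cL_D)
        free_A, cplx_A = model.speciate(c_A, cL_A)
        out["donor_total"][i] = c_D
        out["acceptor_total"][i] = c_A
        out["donor_free"][i] = free_D
        out["donor_complexed"][i] = cplx_D
        out["acceptor_free"][i] = free_A
        out["acceptor_complexed"][i] = cplx_A
        out["ligand_donor"][i] = cL_D
        out["ligand_acceptor"][i] = cL_A
        out["precipitated_mass"][i] = yi[2]
        out["SSR_donor"][i] = ssr(c_D, s_D)
        out["SSR_acceptor"][i] = ssr(c_A, s_A)
        out["solubility_donor_eff"][i] = s_D
        out["solubility_acceptor_eff"][i] = s_A
        out["V_donor"][i] = v_d
        out["V_acceptor"][i] = v_a

    result = CellSimulationResult(
        times=times,
        withdrawn_drug=withdrawn_drug,
        withdrawn_ligand=withdrawn_ligand,
        metadata={
            "B_e": model.B_e,
            "B_UWL": coefficients.B_UWL,
            "B_m": coefficients.B_m,
            "K_1to1": K_1to1,
            "area": config.membrane.area,
            "seed": config.seed,
        },
        **out,
    )
    wd = np.array([withdrawn_at[float(t)][0] for t in times])
    wl = np.array([withdrawn_at[float(t)][1] for t in times])
    _check_mass_balance(result, total_drug0, total_ligand0, wd, wl)
    return result


def _check_mass_balance(
    result: CellSimulationResult,
    total_drug0: float,
    total_ligand0: float,
    withdrawn_drug: np.ndarray,
    withdrawn_ligand: np.ndarray,
) -> None:
    drug = result.total_drug_mass() + withdrawn_drug
    if total_drug0 > 0:
        err = np.max(np.abs(drug - total_drug0)) / total_drug0
        if err > _MASS_BALANCE_RTOL:
            raise RuntimeError(f"drug mass balance violated: rel err {err:.2e}")
    if total_ligand0 > 0:
        lig = result.total_ligand_mass() + withdrawn_ligand
        err = np.max(np.abs(lig - total_ligand0)) / total_ligand0
        if err > _MASS_BALANCE_RTOL:
            raise RuntimeError(f"ligand mass balance violated: rel err {err:.2e}")


def closed_form_linear_solution(
    config: DiffusionCellConfig, P_app: float
) -> CellSimulationResult:
    """Analytic two-compartment solution for the ligand-free linear regime.

    With no ligand, no precipitation and equal media, flux reduces to
    ``J = P_app * (c_D - c_A)`` and the compartments relax exponentially
    with rate ``k = P_app * A * (1/V_D + 1/V_A)`` toward the well-mixed
    equilibrium, conserving mass exactly. ``P_app`` in cm/s.
    """
    if config.ligand_total_donor > 0:
        raise ValueError("closed form is only valid without ligand")
    t = np.asarray(config.sampling_times, dtype=float)
    v_d, v_a = config.V_donor, config.V_acceptor
    a = config.membrane.area
    p = units.cm_per_s_to_cm_per_min(P_app)
    k = p * a * (1.0 / v_d + 1.0 / v_a)
    c0 = config.drug_dose_donor
    c_inf = c0 * v_d / (v_d + v_a)
    c_d = c_inf + (c0 - c_inf) * np.exp(-k * t)
    c_a = (c0 * v_d - c_d * v_d) / v_a
    zeros = np.zeros_like(t)
    s_d = np.full_like(t, config.solubility_donor)
    s_a = np.full_like(t, config.solubility_acceptor)
    return CellSimulationResult(
        times=t,
        donor_total=c_d,
        acceptor_total=c_a,
        donor_free=c_d,
        donor_complexed=zeros,
        acceptor_free=c_a,
        acceptor_complexed=zeros,
        ligand_donor=zeros,
        ligand_acceptor=zeros,
        precipitated_mass=zeros,
        SSR_donor=c_d / s_d,
        SSR_acceptor=c_a / s_a,
        solubility_donor_eff=s_d,
        solubility_acceptor_eff=s_a,
        V_donor=np.full_like(t, v_d),
        V_acceptor=np.full_like(t, v_a),
        metadata={"P_app_cm_s": P_app, "closed_form": True},
    )
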