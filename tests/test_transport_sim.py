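"""Two-compartment simulator: SSR flux model, speciation, leakage, clamp."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ssrflux as sf

positive = st.floats(1e-6, 1e3)
SHORT_TIMES = tuple(float(t) for t in range(0, 481, 10))


def _config(membrane, dose=20.0, ligand_molar=0.0, times=SHORT_TIMES, **kw):
    defaults = dict(
        V_donor=18.0,
        V_acceptor=18.0,
        membrane=membrane,
        drug_dose_donor=dose,
        solubility_donor=2.15,
        solubility_acceptor=2.15,
        sampling_times=times,
        ligand_total_donor=ligand_molar,
    )
    defaults.update(kw)
    return sf.DiffusionCellConfig(**defaults)


class TestScalarOperations:
    def test_ssr(self):
        assert sf.ssr(6.69, 6.69) == 1.0
        assert sf.ssr(20.0, 2.15) == pytest.approx(9.30, abs=0.005)
        with pytest.raises(ValueError):
            sf.ssr(1.0, 0.0)

    def test_b_uwl_coefficient(self):
        b = sf.b_uwl_coefficient(6.5e-6, 2.15, 0.065)
        assert b == pytest.approx(2.15e-4, rel=1e-12)  # ug cm^-2 s^-1
        assert sf.b_uwl_coefficient(6.5e-6, 4.30, 0.065) == pytest.approx(2 * b)
        assert sf.b_uwl_coefficient(6.5e-6, 2.15, 0.065, per="min") == pytest.approx(
            60 * b
        )
        assert sf.b_uwl_coefficient(6.5e-6, 2.15, 1e9) < 1e-12

    @given(positive, positive)
    def test_b_effective_properties(self, a, b):
        be = sf.b_effective(a, b)
        assert be == pytest.approx(a * b / (a + b), rel=1e-12)
        assert be == pytest.approx(sf.b_effective(b, a), rel=1e-12)
        assert be < min(a, b)

    def test_b_effective_limits(self):
        assert sf.b_effective(1.0, 1.0) == pytest.approx(0.5)
        assert sf.b_effective(1e-3, 1e6) == pytest.approx(1e-3, rel=1e-6)

    def test_flux_general_model(self):
        assert sf.flux_general_model(0.5, 3.0, 3.0) == 0.0
        assert sf.flux_general_model(0.5, 5.0, 1.0) == pytest.approx(2.0)
        assert sf.flux_general_model(0.5, 1.0, 5.0) == pytest.approx(-2.0)


class TestClosedFormOracle:
    def test_initial_and_mixed_limits(self, lipophilic_config):
        res = sf.closed_form_linear_solution(lipophilic_config, 1e-4)
        assert res.donor_total[0] == 20.0
        assert res.acceptor_total[0] == 0.0
        cfg_long = _config(lipophilic_config.membrane, times=(0.0, 1e7))
        res_long = sf.closed_form_linear_solution(cfg_long, 1e-4)
        c_inf = 20.0 * 18.0 / 36.0
        assert res_long.donor_total[-1] == pytest.approx(c_inf, rel=1e-9)
        assert res_long.acceptor_total[-1] == pytest.approx(c_inf, rel=1e-9)

    def test_simulator_matches_closed_form(
        self, lipophilic_config, lipophilic_decomposition, carvedilol
    ):
        """Ligand-free simulation equals the two-compartment exponential
        with rate k = P_app*A*(1/V_d + 1/V_a) on a 480-min grid."""
        res = sf.simulate_cell(
            lipophilic_config, carvedilol, coefficients=lipophilic_decomposition
        )
        oracle = sf.closed_form_linear_solution(
            lipophilic_config, lipophilic_decomposition.P_app
        )
        assert np.allclose(res.donor_total, oracle.donor_total, rtol=1e-6)
        mask = oracle.acceptor_total > 0
        assert np.allclose(
            res.acceptor_total[mask], oracle.acceptor_total[mask], rtol=1e-6
        )

    def test_rejects_ligand(self, carvedilol, hpbcd):
        cfg = _config(sf.default_membrane("lipophilic"), ligand_molar=1e-2)
        with pytest.raises(ValueError):
            sf.closed_form_linear_solution(cfg, 1e-4)


class TestSimulateCell:
    def test_symmetric_equilibrium(self, carvedilol):
        """Equal volumes, no ligand: both sides relax to half the dose."""
        cfg = _config(
            sf.default_membrane("lipophilic"), times=(0.0, 500.0, 50_000.0)
        )
        decomp = sf.PermeabilityDecomposition(P_UWL=1e-4, P_membrane_u0=1e-4)
        res = sf.simulate_cell(cfg, carvedilol, coefficients=decomp)
        assert res.donor_total[-1] == pytest.approx(10.0, rel=1e-6)
        assert res.acceptor_total[-1] == pytest.approx(10.0, rel=1e-6)

    def test_cd_lowers_flux_at_equal_dose_not_equal_ssr(self, carvedilol, hpbcd):
        """Donor cyclodextrin lowers initial flux at matched total dose but
        leaves it unchanged at matched delta-SSR (lipophilic membrane)."""
        membrane = sf.default_membrane("lipophilic")
        coeffs = sf.TransportCoefficients(B_UWL=0.024, B_m=0.037)
        lig_molar = sf.units.mass_conc_to_molar(15_000.0, hpbcd.molecular_weight)

        buffer_run = sf.simulate_cell(
            _config(membrane, dose=20.0), carvedilol, coefficients=coeffs
        )
        cd_same_dose = sf.simulate_cell(
            _config(membrane, dose=20.0, ligand_molar=lig_molar),
            carvedilol,
            hpbcd,
            sf.K_FORM1,
            coefficients=coeffs,
        )
        j0 = lambda r: r.acceptor_total[1] * 18.0 / (membrane.area * 10.0)
        assert j0(cd_same_dose) < 0.75 * j0(buffer_run)

        # matched initial SSR: dose_cd = SSR * S_eff
        s_eff = cd_same_dose.solubility_donor_eff[0]
        cd_same_ssr = sf.simulate_cell(
            _config(membrane, dose=(20.0 / 2.15) * s_eff, ligand_molar=lig_molar),
            carvedilol,
            hpbcd,
            sf.K_FORM1,
            coefficients=coeffs,
        )
        assert cd_same_ssr.SSR_donor[0] == pytest.approx(buffer_run.SSR_donor[0])
        # first-interval averages differ slightly: the solubilized donor's
        # SSR decays more slowly at equal absolute mass loss
        assert j0(cd_same_ssr) == pytest.approx(j0(buffer_run), rel=5e-3)

    def test_ligand_leakage_reaches_calibrated_endpoint(self, carvedilol, hpbcd):
        """A 15 mg/mL donor crosses the fast size-exclusion membrane at its
        calibrated permeability, reaching the 8-h acceptor endpoint."""
        membrane = sf.default_membrane("6kDa")
        cfg = _config(
            membrane,
            dose=5.0,
            ligand_molar=sf.units.mass_conc_to_molar(15_000.0, hpbcd.molecular_weight),
            V_donor=20.0,
            V_acceptor=20.0,
            times=tuple(float(t) for t in range(0, 481, 20)),
        )
        coeffs = sf.scenario_coefficients(sf.ScenarioSpec(membrane_kind="6kDa"))
        res = sf.simulate_cell(
            cfg, carvedilol, hpbcd, sf.K_FORM1, coefficients=coeffs
        )
        assert res.ligand_acceptor[-1] == pytest.approx(516.0, rel=1e-3)

    def test_complex_flux_monotone_in_leak_permeability(self, carvedilol, hpbcd):
        """Extra drug flux carried by the permeating complex grows with the
        membrane's leak permeability (the MWCO ordering)."""
        lig_molar = sf.units.mass_conc_to_molar(15_000.0, hpbcd.molecular_weight)
        coeffs = sf.TransportCoefficients(B_UWL=0.024, B_m=0.0055)
        j_by_perm = []
        for p_leak in (0.0, sf.LIGAND_PERMEABILITY_1KDA, sf.LIGAND_PERMEABILITY_6KDA):
            membrane = sf.MembraneBarrier(
                kind="size_exclusion", ligand_permeability=p_leak
            )
            res = sf.simulate_cell(
                _config(membrane, dose=20.0, ligand_molar=lig_molar),
                carvedilol,
                hpbcd,
                sf.K_FORM1,
                coefficients=coeffs,
            )
            j_by_perm.append(res.acceptor_total[1])
        assert j_by_perm[0] < j_by_perm[1] < j_by_perm[2]

    def test_stirring_speeds_flux_only_when_uwl_limited(self):
        """Thinning the UWL raises B_e when the UWL dominates and leaves it
        unchanged when the membrane does."""
        spec_thick = sf.ScenarioSpec(stirring_rpm=0.0)
        spec_thin = sf.ScenarioSpec(stirring_rpm=250.0)
        be_thick = sf.scenario_coefficients(spec_thick).B_e
        be_thin = sf.scenario_coefficients(spec_thin).B_e
        assert be_thin > be_thick
        # membrane-limited: B_m tiny, UWL thickness irrelevant
        bm = 1e-6
        assert sf.b_effective(
            sf.scenario_coefficients(spec_thin).B_UWL, bm
        ) == pytest.approx(
            sf.b_effective(sf.scenario_coefficients(spec_thick).B_UWL, bm), rel=1e-3
        )

    def test_requires_coefficients(self, lipophilic_config, carvedilol):
        with pytest.raises(ValueError):
            sf.simulate_cell(lipophilic_config, carvedilol)


class TestPrecipitationAndWithdrawals:
    def test_instant_clamp_pins_donor_at_solubility(
        self, lipophilic_config, lipophilic_decomposition, carvedilol
    ):
        opts = sf.SimulationOptions(precipitation=True)
        res = sf.simulate_cell(
            lipophilic_config,
            carvedilol,
            coefficients=lipophilic_decomposition,
            options=opts,
        )
        assert res.donor_total[0] == pytest.approx(2.15)
        assert res.precipitated_mass[0] == pytest.approx((20.0 - 2.15) * 18.0)
        # precipitate redissolves to hold saturation while drug leaves
        assert np.all(np.diff(res.precipitated_mass) <= 0)
        assert np.allclose(res.donor_total, 2.15, rtol=1e-9)

    def test_delayed_onset_conserves_mass(
        self, lipophilic_config, lipophilic_decomposition, carvedilol
    ):
        opts = sf.SimulationOptions(precipitation=True, precipitation_onset_min=60.0)
        res = sf.simulate_cell(
            lipophilic_config,
            carvedilol,
            coefficients=lipophilic_decomposition,
            options=opts,
        )
        assert res.precipitated_mass[res.times < 60.0].max() == 0.0
        assert res.precipitated_mass[-1] > 0.0
        total = res.total_drug_mass()
        assert np.max(np.abs(total - total[0])) / total[0] < 1e-8

    @pytest.mark.parametrize(
        "scenario_kw",
        [
            dict(membrane_kind="lipophilic"),
            dict(membrane_kind="lipophilic", ligand_donor=15_000.0),
            dict(membrane_kind="6kDa", ligand_donor=15_000.0),
            dict(membrane_kind="lipophilic", precipitation=True),
            dict(
                membrane_kind="6kDa",
                ligand_donor=15_000.0,
                precipitation=True,
                precipitation_onset_min=45.0,
            ),
        ],
        ids=["plain", "cd-lipophilic", "cd-leak", "clamp", "cd-leak-clamp"],
    )
    def test_mass_conservation_all_scenarios(self, scenario_kw):
        """Drug and ligand mass balances hold to 1e-8 relative in every
        scenario class, including clamped precipitation runs."""
        spec = sf.ScenarioSpec(
            dose_ladder=(20.0,), noise_sd=0.0, seed=1, **scenario_kw
        )
        truth = sf.make_cell_experiment(spec)[0].truth
        drug = truth.total_drug_mass()
        assert np.max(np.abs(drug - drug[0])) / drug[0] < 1e-8
        lig = truth.total_ligand_mass()
        if lig[0] > 0:
            assert np.max(np.abs(lig - lig[0])) / lig[0] < 1e-8

    def test_withdrawals_remove_mass_not_concentration(
        self, lipophilic_decomposition, carvedilol
    ):
        events = (
            sf.WithdrawalEvent(time_min=120.0, volume_ml=1.0),
            sf.WithdrawalEvent(time_min=240.0, volume_ml=1.0),
        )
        cfg = _config(sf.default_membrane("lipophilic"), V_donor=20.0, V_acceptor=20.0)
        res = sf.simulate_cell(
            cfg,
            carvedilol,
            coefficients=lipophilic_decomposition,
            options=sf.SimulationOptions(withdrawals=events),
        )
        assert res.V_donor[-1] == pytest.approx(18.0)
        assert res.withdrawn_drug > 0.0
        total = res.total_drug_mass() + res.withdrawn_drug
        # withdrawn mass accrues stepwise; endpoint balance still closes
        assert total[-1] == pytest.approx(20.0 * 20.0, rel=1e-8)

    def test_overdraw_rejected(self, lipophilic_decomposition, carvedilol):
        cfg = _config(sf.default_membrane("lipophilic"))
        with pytest.raises(ValueError):
            sf.simulate_cell(
                cfg,
                carvedilol,
                coefficients=lipophilic_decomposition,
                options=sf.SimulationOptions(
                    withdrawals=(sf.WithdrawalEvent(60.0, 50.0),)
                ),
            )
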