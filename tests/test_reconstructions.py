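"""Curated core models: pathway content, hand-balanced stoichiometry oracles,
sulfide-shuttle behaviour and biomass calibration."""

import numpy as np
import pytest

from pelocore import (
    BiomassSpec,
    EnergyParams,
    calibrate_biomass,
    max_atp,
    optimal_growth,
    set_biomass_composition,
    validate_model,
)
from pelocore.scenarios import (
    Scenario,
    biomass_sensitivity,
    lactate_yield_by_transport,
    pcar_btd_fe3,
    pcar_fermentation,
    pcar_syntrophic,
    ppro_fermentation,
    run_scenario,
    scenario_condition,
)


class TestModelStructure:
    @pytest.mark.parametrize("species", ["pcar", "ppro"])
    def test_zero_violations_and_elemental_balance(self, species, pcar, ppro):
        m = {"pcar": pcar, "ppro": ppro}[species]
        assert validate_model(m) == []
        # every metabolite carries a formula, so the validator actually
        # checked balance on all non-exchange, non-pseudo reactions
        assert all(met.formula for met in m.metabolites)

    def test_pcar_expected_reactions_present(self, pcar):
        for rid in ("ACOR", "ACKr", "EGDH", "PFL", "FDH", "SRE", "SRE2", "FE3Rs",
                    "HYD", "THD", "ATPS", "BTDD", "SUCDq"):
            assert pcar.has_reaction(rid), rid

    def test_ppro_expected_reactions_present_and_pcar_unique_absent(self, ppro):
        for rid in ("MMM", "MMTC", "PSCT", "LACt", "LDH", "FRDm", "POHDH", "BACT"):
            assert ppro.has_reaction(rid), rid
        for rid in ("EGDH", "PFL", "FDH"):
            assert not ppro.has_reaction(rid), rid

    def test_citrate_lyase_shipped_closed(self, ppro):
        r = ppro.reaction("CITL")
        assert r.lower_bound == r.upper_bound == 0.0

    def test_atpm_lower_bound_encodes_ngam(self, pcar, ppro):
        assert pcar.reaction("ATPM").lower_bound == pytest.approx(0.844)
        assert ppro.reaction("ATPM").lower_bound == pytest.approx(2.80)

    def test_energy_params_validation(self):
        with pytest.raises(ValueError):
            EnergyParams(gam=-1)
        with pytest.raises(ValueError):
            EnergyParams(atp_synthase_h_per_atp=1.0)
        with pytest.raises(ValueError):
            BiomassSpec(acetyl_coa=-5)


class TestPcarCatabolism:
    """Hand redox/carbon balances of the fermentation routes at zero growth."""

    def test_acetoin_yields_one_atp_equimolar_products(self, pcar_catabolic):
        m = pcar_catabolic
        cond = scenario_condition(pcar_fermentation("actn"), m)
        sol = max_atp(m, cond, {m.exchange_for("actn"): -6.0, m.biomass_reaction_id: 0.0})
        assert sol.objective_value == pytest.approx(6.0, abs=1e-6)
        assert sol.flux(m.exchange_for("ac")) == pytest.approx(6.0, abs=1e-6)
        assert sol.flux(m.exchange_for("etoh")) == pytest.approx(6.0, abs=1e-6)

    def test_butanediol_with_h2_gives_two_acetate_three_h2_two_atp(self, pcar_catabolic):
        m = pcar_catabolic
        cond = scenario_condition(pcar_syntrophic("btd"), m)
        sol = max_atp(m, cond, {m.exchange_for("btd"): -1.0, m.biomass_reaction_id: 0.0})
        assert sol.objective_value == pytest.approx(2.0, abs=1e-6)
        assert sol.flux(m.exchange_for("ac")) == pytest.approx(2.0, abs=1e-6)
        assert sol.flux(m.exchange_for("h2")) == pytest.approx(3.0, abs=1e-6)
        assert abs(sol.flux(m.exchange_for("etoh"))) <= 1e-9

    def test_no_acetate_oxidation_to_co2_with_elemental_sulfur(self, pcar_catabolic):
        # the quinone pool has no route to S0: complete oxidation of acetate
        # with sulfur as the acceptor is impossible (no net CO2 evolution)
        m = pcar_catabolic
        scen = Scenario("acetate on S0", "pcar", (("ac", 10.0),), acceptor="s0",
                        growth=("max",), objective_mode="max_biomass")
        cond = scenario_condition(scen, m)
        sol = max_atp(m, cond, {m.exchange_for("ac"): -10.0, m.biomass_reaction_id: 0.0})
        if sol.optimal:
            assert sol.flux(m.exchange_for("co2")) <= 1e-6
            assert sol.objective_value <= 1e-6
        else:
            assert sol.status == "infeasible"

    def test_fermentation_redox_closure_on_carrier_rows(self, pcar_catabolic):
        # S.v = 0 on the NAD(H)/NADP(H) rows: no net carrier production
        m = pcar_catabolic
        cond = scenario_condition(pcar_fermentation("actn"), m)
        sol = max_atp(m, cond, {m.exchange_for("actn"): -5.0, m.biomass_reaction_id: 0.0})
        S, mets, rxns = m.stoichiometric_matrix()
        v = sol.fluxes[rxns].values
        for carrier in ("nad_c", "nadh_c", "nadp_c", "nadph_c"):
            row = S[mets.index(carrier)]
            assert abs(row @ v) <= 1e-6


class TestSulfideShuttle:
    def test_fe3_increases_acetate_and_decreases_ethanol(self, pcar):
        with_fe = run_scenario(pcar_btd_fe3(True), model=pcar)
        without = run_scenario(pcar_btd_fe3(False), model=pcar)
        assert with_fe.ratios["ac:btd"] > without.ratios["ac:btd"] + 1e-6
        assert with_fe.ratios["etoh:btd"] < without.ratios["etoh:btd"] - 1e-6

    @pytest.mark.parametrize("knockout", [("FE3Rs",), ("SRE", "SRE2")])
    def test_fe2_production_requires_the_shuttle(self, pcar, knockout):
        probe = pcar.copy()
        for rid in knockout:
            r = probe.reaction(rid)
            r.lower_bound = r.upper_bound = 0.0
        res = run_scenario(pcar_btd_fe3(True), model=probe)
        fe2 = res.solution.flux(probe.exchange_for("fe2")) if res.optimal else 0.0
        assert abs(fe2) <= 1e-9


class TestPproFermentation:
    def test_ethanol_and_lactate_ferment_at_one_to_two(self, ppro_catabolic):
        # acetate:propionate = 1:2, forced by the redox balance of the
        # methylmalonyl-CoA route at zero growth
        m = ppro_catabolic
        for sub in ("etoh", "lac"):
            cond = scenario_condition(ppro_fermentation(sub), m)
            sol = max_atp(m, cond, {m.exchange_for(sub): -3.0, m.biomass_reaction_id: 0.0})
            ac = sol.flux(m.exchange_for("ac"))
            ppa = sol.flux(m.exchange_for("ppa"))
            assert ppa / ac == pytest.approx(2.0, abs=1e-6), sub

    def test_propanol_consumes_acetate_and_produces_propionate(self, ppro):
        res = run_scenario(ppro_fermentation("poh"), model=ppro)
        assert res.optimal
        assert res.solution.flux(ppro.exchange_for("ac")) < -1e-6
        assert res.solution.flux(ppro.exchange_for("ppa")) > 1e-6

    def test_butanol_secretes_butyrate(self, ppro):
        res = run_scenario(ppro_fermentation("btoh"), model=ppro)
        assert res.optimal
        assert res.solution.flux(ppro.exchange_for("but")) > 1e-6

    def test_lactate_transport_variant_yield_ordering(self):
        y = lactate_yield_by_transport()
        assert y["antiport"] > y["symport"] > y["diffusion"]


class TestBiomass:
    def test_single_coefficient_perturbation_bounded(self, pcar):
        change = biomass_sensitivity(pcar_fermentation("actn"), 0.10)
        assert change <= 0.15

    def test_zero_perturbation_is_zero_change(self, pcar):
        assert biomass_sensitivity(pcar_fermentation("actn"), 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_gam_perturbation_moves_growth_oppositely(self, pcar):
        cond = scenario_condition(pcar_fermentation("actn"), pcar)
        ann = pcar.annotations["biomass"]
        base = optimal_growth(pcar, cond, "actn", 10.0).objective_value
        up = pcar.copy()
        set_biomass_composition(
            up, BiomassSpec(ann["acetyl_coa"], ann["nadph"], ann["nh4"], ann["gam"] * 1.1)
        )
        mu_up = optimal_growth(up, cond, "actn", 10.0).objective_value
        assert mu_up < base

    def test_calibration_fixed_point_recovers_defaults(self, pcar):
        # target generated from the model's own defaults -> returns defaults
        from pelocore.scenarios import acetoin_ratio_predictor

        predict = acetoin_ratio_predictor()
        observed = predict(pcar)
        spec = calibrate_biomass(pcar, [(predict, observed)])
        assert spec.acetyl_coa == pytest.approx(21.0)

    def test_calibration_single_target_monotone_search(self, pcar):
        # acetate:acetoin falls as more acetyl-CoA is diverted to biomass; a
        # reachable target is met within grid resolution
        from pelocore.scenarios import acetoin_ratio_predictor

        predict = acetoin_ratio_predictor()
        target = 0.90
        spec = calibrate_biomass(pcar, [(predict, target)])
        probe = pcar.copy()
        set_biomass_composition(probe, spec)
        assert predict(probe) == pytest.approx(target, abs=0.01)

    def test_calibration_empty_free_set_returns_input(self, pcar):
        from pelocore.scenarios import acetoin_ratio_predictor

        spec = calibrate_biomass(pcar, [(acetoin_ratio_predictor(), 1.0)], free=())
        assert spec.acetyl_coa == 21.0 and spec.nadph == 8.0

    def test_calibration_warns_when_target_unreachable(self, pcar):
        from pelocore.scenarios import acetoin_ratio_predictor

        with pytest.warns(UserWarning, match="calibration residual"):
            calibrate_biomass(pcar, [(acetoin_ratio_predictor(), 5.0)])
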