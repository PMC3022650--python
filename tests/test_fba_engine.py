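"""LP formulation, objective modes and the gap (producibility) analysis."""

import numpy as np
import pytest

from pelocore import (
    Condition,
    Metabolite,
    Model,
    Reaction,
    biomass_producibility,
    max_atp,
    min_substrate_at_growth,
    optimal_growth,
    solve_fba,
)
from pelocore.fba import BOUND_TOL, MASS_BALANCE_TOL
from pelocore.scenarios import (
    pcar_fermentation,
    pcar_syntrophic,
    scenario_condition,
)
from pelocore.synth import gen_toy_network, toy_condition


def chain_model():
    """EX_A -> A -> B -> EX_B, unit coefficients."""
    return Model(
        "chain",
        "test",
        [
            Metabolite("a_e", compartment="e"),
            Metabolite("a_c", compartment="c"),
            Metabolite("b_c", compartment="c"),
            Metabolite("b_e", compartment="e"),
        ],
        [
            Reaction("EX_a_e", stoichiometry={"a_e": -1.0}, lower_bound=-1000, upper_bound=1000),
            Reaction("T_a", stoichiometry={"a_e": -1.0, "a_c": 1.0}, upper_bound=1000),
            Reaction("R_ab", stoichiometry={"a_c": -1.0, "b_c": 1.0}, upper_bound=1000),
            Reaction("T_b", stoichiometry={"b_c": -1.0, "b_e": 1.0}, upper_bound=1000),
            Reaction("EX_b_e", stoichiometry={"b_e": -1.0}, lower_bound=-1000, upper_bound=1000),
            Reaction("BIOMASS", stoichiometry={"b_c": -1.0}, lower_bound=0, upper_bound=0),
            Reaction("ATPM", stoichiometry={"a_c": -1.0}, lower_bound=0, upper_bound=0),
        ],
        "BIOMASS",
        "ATPM",
    )


class TestSolveFBA:
    def test_linear_chain_conserves_mass(self):
        m = chain_model()
        cond = Condition(
            free_exchanges=(), uptake_limits={"a": 10.0}, objective=("EX_b_e", "max")
        )
        sol = solve_fba(m, cond)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_no_carbon_source_means_no_growth(self, pcar):
        cond = Condition(objective=(pcar.biomass_reaction_id, "max"))
        sol = solve_fba(pcar, cond)
        # nGAM > 0 cannot be met without a substrate
        assert sol.status == "infeasible" or sol.objective_value <= 1e-9

    def test_unbounded_objective_reported_not_clipped(self):
        # a free-exchange loop: two unbounded exchanges on the same metabolite
        m = chain_model()
        m.reactions.append(
            Reaction("EX_b2_e", stoichiometry={"b_e": -1.0}, lower_bound=-1000, upper_bound=1000)
        )
        cond = Condition(free_exchanges=("a", "b"), objective=("EX_b_e", "max"))
        sol = solve_fba(m, cond)
        assert sol.status == "unbounded"
        assert np.isnan(sol.objective_value)

    def test_unknown_condition_reaction_rejected(self, pcar):
        with pytest.raises(KeyError):
            solve_fba(pcar, Condition(fixed_fluxes={"NOPE": 1.0}, objective=("ATPM", "max")))

    @pytest.mark.parametrize("seed", range(12))
    def test_objective_matches_enumeration_oracle(self, seed):
        m = gen_toy_network(4, 8, seed=seed)
        sol = solve_fba(m, toy_condition(m))
        assert sol.optimal
        expected = m.annotations["enumerated_optimum"]
        assert sol.objective_value == pytest.approx(expected, abs=1e-6, rel=1e-6)

    @pytest.mark.parametrize("seed", [0, 3, 11])
    @pytest.mark.parametrize("n_mets,n_rxns", [(2, 6), (3, 7), (5, 8)])
    def test_oracle_holds_across_network_sizes(self, seed, n_mets, n_rxns):
        m = gen_toy_network(n_mets, n_rxns, seed=seed)
        sol = solve_fba(m, toy_condition(m))
        assert sol.objective_value == pytest.approx(
            m.annotations["enumerated_optimum"], abs=1e-6, rel=1e-6
        )

    def test_optimal_solutions_satisfy_tolerances(self, pcar):
        cond = scenario_condition(pcar_fermentation("actn"), pcar)
        sol = optimal_growth(pcar, cond, "actn", 10.0)
        assert sol.optimal
        S, _, rxns = pcar.stoichiometric_matrix()
        v = sol.fluxes.values
        assert np.max(np.abs(S @ v)) <= MASS_BALANCE_TOL * max(1.0, np.max(np.abs(v)))
        from pelocore.fba import _apply_condition

        bounds = _apply_condition(
            pcar,
            cond.with_(
                fixed_fluxes={pcar.exchange_for("actn"): -10.0},
                objective=(pcar.biomass_reaction_id, "max"),
            ),
        )
        for x, (lo, hi) in zip(v, bounds):
            assert lo - BOUND_TOL <= x <= hi + BOUND_TOL


class TestIndependentSolverCrossCheck:
    @pytest.mark.parametrize("scenario_sub,uptake", [("actn", 10.0), ("btd", 8.0)])
    def test_optimal_growth_matches_cobrapy(self, pcar, scenario_sub, uptake):
        """The same LP handed to COBRApy/GLPK returns the same optimum."""
        cobra = pytest.importorskip("cobra")
        cond = scenario_condition(pcar_fermentation(scenario_sub), pcar)
        mine = optimal_growth(pcar, cond, scenario_sub, uptake)
        assert mine.optimal

        from pelocore.fba import _apply_condition

        full = cond.with_(
            fixed_fluxes={pcar.exchange_for(scenario_sub): -uptake},
            objective=(pcar.biomass_reaction_id, "max"),
        )
        bounds = _apply_condition(pcar, full)
        cm = cobra.Model(pcar.id)
        mets = {
            m.id: cobra.Metabolite(m.id, compartment=m.compartment)
            for m in pcar.metabolites
        }
        big = 1e6  # GLPK dislikes infinite bounds
        reactions = []
        for r, (lo, hi) in zip(pcar.reactions, bounds):
            cr = cobra.Reaction(
                r.id,
                lower_bound=max(lo, -big) if np.isfinite(lo) else -big,
                upper_bound=min(hi, big) if np.isfinite(hi) else big,
            )
            reactions.append((cr, r.stoichiometry))
        cm.add_reactions([cr for cr, _ in reactions])
        for cr, st in reactions:
            cr.add_metabolites({mets[k]: v for k, v in st.items()})
        cm.objective = pcar.biomass_reaction_id
        assert cm.slim_optimize() == pytest.approx(mine.objective_value, abs=1e-6)


class TestObjectiveModes:
    def test_acetoin_growth_secretes_acetate_and_ethanol(self, pcar):
        cond = scenario_condition(pcar_fermentation("actn"), pcar)
        sol = optimal_growth(pcar, cond, "actn", 5.0)
        assert sol.optimal and sol.objective_value > 0
        assert sol.flux(pcar.exchange_for("ac")) > 1e-6
        assert sol.flux(pcar.exchange_for("etoh")) > 1e-6

    def test_uptake_below_maintenance_floor_blocks_growth(self, pcar):
        cond = scenario_condition(pcar_fermentation("actn"), pcar)
        # 1 ATP per acetoin; nGAM = 0.844 needs >= 0.844 acetoin at zero growth
        sol = optimal_growth(pcar, cond, "actn", 0.5)
        assert (not sol.optimal) or sol.objective_value <= 1e-9

    def test_growth_increases_with_uptake_above_floor(self, pcar):
        cond = scenario_condition(pcar_fermentation("actn"), pcar)
        mu1 = optimal_growth(pcar, cond, "actn", 5.0).objective_value
        mu2 = optimal_growth(pcar, cond, "actn", 10.0).objective_value
        assert mu2 > mu1 + 1e-9

    def test_min_substrate_zero_growth_covers_ngam_exactly(self, pcar):
        # hand stoichiometry: the acetoin route yields net 1 ATP per acetoin,
        # so sustaining 0.844 mmol ATP/gdw/h takes exactly 0.844 acetoin
        cond = scenario_condition(pcar_fermentation("actn"), pcar)
        sol = min_substrate_at_growth(pcar, cond, "actn", 0.0)
        assert -sol.flux(pcar.exchange_for("actn")) == pytest.approx(0.844, abs=1e-6)

    def test_min_substrate_zero_growth_zero_ngam_is_zero(self, pcar_catabolic):
        cond = scenario_condition(pcar_fermentation("actn"), pcar_catabolic)
        sol = min_substrate_at_growth(pcar_catabolic, cond, "actn", 0.0)
        assert abs(sol.flux(pcar_catabolic.exchange_for("actn"))) <= 1e-9

    def test_min_substrate_finite_on_butanediol_with_h2(self, pcar):
        cond = scenario_condition(pcar_syntrophic("btd"), pcar)
        sol = min_substrate_at_growth(pcar, cond, "btd", 0.087)
        assert sol.optimal and 0 < -sol.flux(pcar.exchange_for("btd")) < 100

    def test_min_substrate_and_optimal_growth_are_consistent(self, pcar):
        cond = scenario_condition(pcar_syntrophic("btd"), pcar)
        mu = 0.087
        sol = min_substrate_at_growth(pcar, cond, "btd", mu)
        uptake = -sol.flux(pcar.exchange_for("btd"))
        back = optimal_growth(pcar, cond, "btd", uptake)
        assert back.objective_value >= mu - 1e-6

    def test_infeasible_growth_rate_reported(self, pcar):
        cond = scenario_condition(pcar_fermentation("actn"), pcar).with_(
            uptake_limits={"actn": 1.0}
        )
        sol = min_substrate_at_growth(pcar, cond, "actn", 5.0)
        assert sol.status == "infeasible"


class TestMaxATP:
    def test_fixed_acetoin_and_acetate_give_one_atp_each(self, pcar_catabolic):
        m = pcar_catabolic
        cond = scenario_condition(pcar_fermentation("actn"), m)
        sol = max_atp(m, cond, {m.exchange_for("actn"): -5.0, m.exchange_for("ac"): 5.0,
                                m.biomass_reaction_id: 0.0})
        assert sol.objective_value == pytest.approx(5.0, abs=1e-6)

    def test_all_zero_fluxes_give_zero_atp(self, pcar_catabolic):
        m = pcar_catabolic
        fixed = {rid: 0.0 for rid in m.exchange_ids()}
        fixed[m.biomass_reaction_id] = 0.0
        sol = max_atp(m, cond=Condition(), fixed=fixed)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_when_fixed_fluxes_violate_conservation(self, pcar_catabolic):
        m = pcar_catabolic
        cond = scenario_condition(pcar_fermentation("actn"), m)
        # more acetate out than acetoin carbon allows
        sol = max_atp(m, cond, {m.exchange_for("actn"): -1.0, m.exchange_for("ac"): 5.0,
                                m.biomass_reaction_id: 0.0})
        assert sol.status == "infeasible"

    def test_qatp_nonincreasing_and_concave_in_mu(self, pcar):
        cond = scenario_condition(pcar_fermentation("actn"), pcar)
        fixed_uptake = {pcar.exchange_for("actn"): -10.0}
        mus = np.linspace(0.0, 0.06, 7)
        q = []
        for mu in mus:
            sol = max_atp(pcar, cond, {**fixed_uptake, pcar.biomass_reaction_id: mu})
            assert sol.optimal
            q.append(sol.objective_value)
        q = np.array(q)
        assert np.all(np.diff(q) <= 1e-9)
        second = np.diff(q, 2)
        assert np.all(second <= 1e-7)

    def test_qatp_increases_with_uptake_at_fixed_mu(self, pcar):
        cond = scenario_condition(pcar_fermentation("actn"), pcar)
        q = [
            max_atp(pcar, cond, {pcar.exchange_for("actn"): -u, pcar.biomass_reaction_id: 0.02}
                    ).objective_value
            for u in (2.0, 4.0, 8.0)
        ]
        assert q[0] < q[1] < q[2]
        assert all(x >= 0 for x in q)


class TestProducibility:
    def test_intact_model_on_acetoin_produces_all_precursors(self, pcar):
        cond = scenario_condition(pcar_fermentation("actn"), pcar).with_(
            uptake_limits={"actn": 10.0}
        )
        report = biomass_producibility(pcar, cond)
        assert report["producible"].all()

    def test_deleting_acetyl_coa_route_blocks_dependent_precursors(self, pcar):
        probe = pcar.copy()
        for rid in ("ACOR", "ACALD"):  # both routes from acetoin to acetyl-CoA
            r = probe.reaction(rid)
            r.lower_bound = r.upper_bound = 0.0
        cond = scenario_condition(pcar_fermentation("actn"), probe).with_(
            uptake_limits={"actn": 10.0}
        )
        report = biomass_producibility(probe, cond)
        assert not report.loc["accoa_c", "producible"]

    def test_empty_medium_blocks_carbon_precursors(self, pcar):
        report = biomass_producibility(pcar, Condition())
        assert not report.loc["accoa_c", "producible"]
        assert not report.loc["nadph_c", "producible"]
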