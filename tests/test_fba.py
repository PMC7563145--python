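"""FBA, total-flux minimization and variability at the optimum."""

import numpy as np
import pytest

from diatomgem.core import (
    ElementalFormula,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    stoichiometric_matrix,
)
from diatomgem.fba import (
    SimulationConstraints,
    fba,
    fixed_objective_variability,
    pfba,
)
from conftest import enumerate_split_bfs


def linear_chain():
    """uptake → A → B → export, uptake capped at 5."""
    m = MetabolicModel(id="chain", compartments={"c": "cytosol"})
    for mid in ("a_c", "b_c"):
        m.add_metabolite(Metabolite(mid, compartment="c",
                                    formula=ElementalFormula.parse("C1")))
    m.add_reaction(Reaction("up", stoichiometry={"a_c": 1}, lower_bound=0, upper_bound=5,
                            kind="exchange"))
    m.add_reaction(Reaction("conv", stoichiometry={"a_c": -1, "b_c": 1},
                            lower_bound=0, upper_bound=1000))
    m.add_reaction(Reaction("ex", stoichiometry={"b_c": -1}, lower_bound=0,
                            upper_bound=1000, kind="exchange"))
    return m


def parallel_paths():
    """A → B directly, or A → C → B; redundant route is longer."""
    m = MetabolicModel(id="parallel", compartments={"c": "cytosol"})
    for mid in ("a_c", "b_c", "c_c"):
        m.add_metabolite(Metabolite(mid, compartment="c",
                                    formula=ElementalFormula.parse("C1")))
    m.add_reaction(Reaction("up", stoichiometry={"a_c": 1}, lower_bound=0, upper_bound=10,
                            kind="exchange"))
    m.add_reaction(Reaction("direct", stoichiometry={"a_c": -1, "b_c": 1},
                            lower_bound=0, upper_bound=10))
    m.add_reaction(Reaction("via1", stoichiometry={"a_c": -1, "c_c": 1},
                            lower_bound=0, upper_bound=10))
    m.add_reaction(Reaction("via2", stoichiometry={"c_c": -1, "b_c": 1},
                            lower_bound=0, upper_bound=10))
    m.add_reaction(Reaction("ex", stoichiometry={"b_c": -1}, lower_bound=0,
                            upper_bound=10, kind="exchange"))
    return m


def reversible_pair():
    m = MetabolicModel(id="rev", compartments={"c": "cytosol"})
    for mid in ("a_c", "b_c"):
        m.add_metabolite(Metabolite(mid, compartment="c",
                                    formula=ElementalFormula.parse("C1")))
    m.add_reaction(Reaction("up", stoichiometry={"a_c": 1}, lower_bound=0, upper_bound=5,
                            kind="exchange"))
    m.add_reaction(Reaction("conv", stoichiometry={"a_c": -1, "b_c": 1},
                            lower_bound=-10, upper_bound=10))
    m.add_reaction(Reaction("ex", stoichiometry={"b_c": -1}, lower_bound=0,
                            upper_bound=10, kind="exchange"))
    return m


class TestFba:
    def test_linear_chain_max_export(self):
        sol = fba(linear_chain(), objective="ex", sense="max")
        assert sol.optimal and sol.objective_value == pytest.approx(5.0)

    def test_closed_photon_means_no_growth(self, toy_model):
        sol = fba(
            toy_model,
            SimulationConstraints(exchange_bounds={"EX_photon": (0.0, 0.0)}),
            objective="biomass",
            sense="max",
        )
        assert sol.optimal and sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_max_biomass_equals_manifest_optimum(self, toy_model, manifest):
        sol = fba(
            toy_model,
            SimulationConstraints(
                atpm=0.0,
                exchange_bounds={"EX_photon": (0.0, manifest.analytic["photon_budget"])},
            ),
            objective="biomass", sense="max",
        )
        assert sol.objective_value == pytest.approx(
            manifest.analytic["max_growth_at_photon_budget"], rel=1e-6
        )

    def test_infeasible_reported_not_raised(self, toy_model):
        sol = fba(
            toy_model,
            SimulationConstraints(growth=10.0,
                                  exchange_bounds={"EX_photon": (0.0, 1.0)}),
            objective="biomass", sense="max",
        )
        assert sol.status == "infeasible"

    def test_unknown_objective_rejected(self, toy_model):
        with pytest.raises(ModelValidationError):
            fba(toy_model, objective="nope", sense="max")

    def test_steady_state_residual(self, toy_model, default_constraints):
        sol = pfba(toy_model, default_constraints)
        sm = stoichiometric_matrix(toy_model)
        v = np.array([sol.fluxes[r] for r in toy_model.reactions])
        assert np.abs(sm.matrix @ v).max() <= 1e-6


class TestPfba:
    def test_all_free_gives_zero_vector(self, toy_model):
        sol = pfba(toy_model, SimulationConstraints(growth=0.0, atpm=0.0))
        assert sol.optimal
        assert sol.total_absolute_flux == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("builder,fixes", [
        (linear_chain, {"ex": 3.0}),
        (parallel_paths, {"ex": 4.0}),
        (reversible_pair, {"ex": 2.0}),
    ])
    def test_matches_bfs_enumeration(self, builder, fixes):
        """pFBA optimum equals brute-force BFS enumeration on tiny fixtures."""
        model = builder()
        constraints = SimulationConstraints(fix=fixes)
        sol = pfba(model, constraints)
        assert sol.optimal
        sm = stoichiometric_matrix(model)
        lb = np.array([r.lower_bound for r in model.reactions.values()])
        ub = np.array([r.upper_bound for r in model.reactions.values()])
        for rid, value in fixes.items():
            j = sm.reaction_index[rid]
            lb[j] = ub[j] = value
        best, _ = enumerate_split_bfs(sm.dense(), lb, ub)
        assert sol.total_absolute_flux == pytest.approx(best, abs=1e-9)

    def test_prefers_shorter_parallel_path(self):
        sol = pfba(parallel_paths(), SimulationConstraints(fix={"ex": 4.0}))
        assert sol["direct"] == pytest.approx(4.0)
        assert sol["via1"] == pytest.approx(0.0, abs=1e-9)

    def test_objective_invariant_to_reaction_reversal(self, toy_model,
                                                      default_constraints):
        base = pfba(toy_model, default_constraints)
        flipped = toy_model.copy()
        rxn = flipped.reactions["tpt_tx"]
        rxn.stoichiometry = {m: -c for m, c in rxn.stoichiometry.items()}
        rxn.lower_bound, rxn.upper_bound = -rxn.upper_bound, -rxn.lower_bound
        alt = pfba(flipped, default_constraints)
        assert alt.total_absolute_flux == pytest.approx(base.total_absolute_flux,
                                                        rel=1e-9)

    def test_optimality_against_feasible_alternatives(self, toy_model,
                                                      default_constraints):
        """Σ|v| from pfba is a lower bound over other feasible solutions."""
        best = pfba(toy_model, default_constraints).total_absolute_flux
        for objective, sense in (("EX_photon", "max"), ("cef", "max"),
                                 ("EX_chryso", "max")):
            other = fba(toy_model, default_constraints, objective=objective, sense=sense)
            if other.optimal:
                assert best <= other.total_absolute_flux + 1e-9

    def test_infeasible_diagnostic_lists_fixes(self, toy_model):
        sol = pfba(toy_model, SimulationConstraints(growth=50.0, atpm=1.5))
        assert sol.status == "infeasible"
        assert "biomass" in sol.diagnostic

    def test_carbon_conservation(self, toy_model, default_constraints):
        """C entering via exchanges = C drained by biomass (steady state)."""
        sol = pfba(toy_model, default_constraints)
        net_exchange_c = 0.0
        for rid, rxn in toy_model.reactions.items():
            if rxn.kind != "exchange":
                continue
            for mid, coeff in rxn.stoichiometry.items():
                n_c = toy_model.metabolites[mid].formula["C"]
                net_exchange_c += float(coeff) * n_c * sol[rid]
        biomass_c = 0.0
        for mid, coeff in toy_model.reactions["biomass"].stoichiometry.items():
            biomass_c += -float(coeff) * toy_model.metabolites[mid].formula["C"]
        assert net_exchange_c == pytest.approx(biomass_c * sol["biomass"], abs=1e-6)

    def test_growth_scaling_doubles_co2(self, toy_model):
        lo = pfba(toy_model, SimulationConstraints(growth=0.012, atpm=0.0))
        hi = pfba(toy_model, SimulationConstraints(growth=0.024, atpm=0.0))
        assert hi["EX_co2"] == pytest.approx(2 * lo["EX_co2"], rel=1e-6)


class TestVariability:
    def test_single_path_width_zero(self):
        model = linear_chain()
        constraints = SimulationConstraints(fix={"ex": 3.0})
        sol = pfba(model, constraints)
        fva = fixed_objective_variability(model, constraints, sol.total_absolute_flux,
                                          list(model.reactions))
        assert (fva["width"].abs() <= 1e-6).all()

    def test_identical_parallel_reactions_share_flux(self):
        m = MetabolicModel(id="twin", compartments={"c": "cytosol"})
        for mid in ("a_c", "b_c"):
            m.add_metabolite(Metabolite(mid, compartment="c",
                                        formula=ElementalFormula.parse("C1")))
        m.add_reaction(Reaction("up", stoichiometry={"a_c": 1}, lower_bound=0,
                                upper_bound=10, kind="exchange"))
        m.add_reaction(Reaction("t1", stoichiometry={"a_c": -1, "b_c": 1},
                                lower_bound=0, upper_bound=10))
        m.add_reaction(Reaction("t2", stoichiometry={"a_c": -1, "b_c": 1},
                                lower_bound=0, upper_bound=10))
        m.add_reaction(Reaction("ex", stoichiometry={"b_c": -1}, lower_bound=0,
                                upper_bound=10, kind="exchange"))
        constraints = SimulationConstraints(fix={"ex": 4.0})
        sol = pfba(m, constraints)
        fva = fixed_objective_variability(m, constraints, sol.total_absolute_flux,
                                          ["t1", "t2"])
        assert fva.loc["t1", "width"] == pytest.approx(4.0, abs=1e-6)
        assert fva.loc["t2", "width"] == pytest.approx(4.0, abs=1e-6)

    def test_cef_uniquely_zero_at_default(self, toy_model, default_constraints):
        sol = pfba(toy_model, default_constraints)
        fva = fixed_objective_variability(toy_model, default_constraints,
                                          sol.total_absolute_flux, ["cef"])
        assert fva.loc["cef", "minimum"] == pytest.approx(0.0, abs=1e-6)
        assert fva.loc["cef", "maximum"] == pytest.approx(0.0, abs=1e-6)


class TestRatioConstraints:
    def test_forced_psi_excess_activates_cef(self, toy_model):
        """Forcing extra PSI turnover (relative to PSII) requires cyclic flow."""
        constraints = SimulationConstraints(
            growth=0.024, atpm=1.5, ratios=(("psi", "psii", 3.0),)
        )
        sol = pfba(toy_model, constraints)
        assert sol.optimal
        assert sol["psi"] == pytest.approx(3.0 * sol["psii"], rel=1e-6)
        assert sol["cef"] > 1e-6

    def test_lef_couples_photosystems_one_to_two(self, toy_model):
        """PSII flux = PSI flux is infeasible: linear flow fixes the coupling."""
        constraints = SimulationConstraints(
            growth=0.024, atpm=1.5, ratios=(("psii", "psi", 1.0),)
        )
        assert pfba(toy_model, constraints).status == "infeasible"

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ModelValidationError):
            SimulationConstraints(ratios=(("a", "b", 0.0),))


class TestCobraCrossCheck:
    """cobrapy (GLPK) as an independent oracle for the same LPs."""

    def test_max_growth_agrees(self, toy_model, cobra_toy, manifest):
        budget = manifest.analytic["photon_budget"]
        ours = fba(
            toy_model,
            SimulationConstraints(atpm=0.0,
                                  exchange_bounds={"EX_photon": (0.0, budget)}),
            objective="biomass", sense="max",
        )
        with cobra_toy as m:
            m.reactions.get_by_id("EX_photon").bounds = (0.0, budget)
            m.reactions.get_by_id("atpm_c").bounds = (0.0, 0.0)
            m.objective = "biomass"
            theirs = m.slim_optimize()
        assert ours.objective_value == pytest.approx(theirs, rel=1e-6)

    def test_pfba_total_flux_agrees(self, toy_model, cobra_toy, default_constraints):
        from cobra.flux_analysis import pfba as cobra_pfba

        ours = pfba(toy_model, default_constraints)
        with cobra_toy as m:
            m.reactions.get_by_id("biomass").bounds = (0.024, 0.024)
            m.reactions.get_by_id("atpm_c").bounds = (1.5, 1.5)
            m.objective = "biomass"
            theirs = cobra_pfba(m)
        assert ours.total_absolute_flux == pytest.approx(theirs.objective_value,
                                                         rel=1e-6)
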