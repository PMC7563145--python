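"""Essentiality, scans, valve knockout, and maximum-yield screening."""

import numpy as np
import pytest

from diatomgem.analyses import (
    atpm_scan,
    essentiality_screen,
    load_default_catalog,
    max_yield,
    shuttle_knockout_experiment,
    si_scan,
)
from diatomgem.core import ModelValidationError, Reaction
from diatomgem.fba import InfeasibleError, SimulationConstraints, pfba


@pytest.fixture(scope="module")
def catalog(toy_model):
    return load_default_catalog(toy_model)


@pytest.fixture(scope="module")
def report(toy_model):
    return essentiality_screen(
        toy_model, SimulationConstraints(growth=0.024, atpm=1.5)
    )


@pytest.fixture(scope="module")
def si_result(toy_model):
    return si_scan(toy_model, np.linspace(0.0, 0.05, 6))


@pytest.fixture(scope="module")
def atpm_result(toy_model):
    return atpm_scan(toy_model, np.arange(0.0, 8.5, 0.5))


class TestEssentiality:
    def test_biomass_is_essential(self, report):
        assert report.verdicts["biomass"] == "essential"

    def test_redundant_routes_are_non_essential(self, report):
        # valve and cyclic electron flow back each other up; overflow and
        # urea-cycle reactions carry no mandatory flux
        for rid in ("cef", "oaa_mal_mito_tx", "oaa_mal_chlo_tx",
                    "arginase_c", "EX_chryso", "EX_urea"):
            assert report.verdicts[rid] == "non-essential", rid

    def test_verdicts_cover_all_screened(self, report, toy_model):
        assert set(report.verdicts) == set(toy_model.reactions)
        assert sum(report.totals().values()) == len(toy_model.reactions)

    def test_essential_reactions_carry_baseline_flux(self, report, toy_model):
        """Anything essential must be active in the baseline distribution."""
        baseline = pfba(toy_model, SimulationConstraints(growth=0.024, atpm=1.5))
        for rid in report.essential:
            assert abs(baseline[rid]) > 1e-9, rid

    def test_matches_cobra_deletion_oracle(self, report, cobra_toy):
        """Independent GLPK feasibility check per deleted reaction."""
        with cobra_toy as m:
            m.reactions.get_by_id("biomass").bounds = (0.024, 0.024)
            m.reactions.get_by_id("atpm_c").bounds = (1.5, 1.5)
            m.objective = "biomass"
            for rid, verdict in report.verdicts.items():
                if verdict == "blocked":
                    continue
                rxn = m.reactions.get_by_id(rid)
                old = rxn.bounds
                # intersect with any existing fix: deleting a reaction whose
                # flux is demanded (growth, maintenance) is infeasible
                lo, hi = max(old[0], 0.0), min(old[1], 0.0)
                if lo > hi:
                    infeasible = True
                else:
                    rxn.bounds = (lo, hi)
                    value = m.slim_optimize()
                    rxn.bounds = old
                    infeasible = value is None or np.isnan(value)
                assert infeasible == (verdict == "essential"), rid

    def test_baseline_infeasible_aborts(self, toy_model):
        with pytest.raises(InfeasibleError):
            essentiality_screen(toy_model, SimulationConstraints(growth=5.0, atpm=1.5))

    def test_dead_end_reaction_reported_blocked(self, toy_model):
        from diatomgem.core import ElementalFormula, Metabolite

        work = toy_model.copy()
        work.add_metabolite(Metabolite("deadend_c", compartment="c",
                                       formula=ElementalFormula.parse("C1")))
        work.add_reaction(
            Reaction("dead", stoichiometry={"co2_c": -1, "deadend_c": 1},
                     lower_bound=0, upper_bound=1000)
        )
        report = essentiality_screen(
            work, SimulationConstraints(growth=0.024, atpm=1.5), reactions=["dead"]
        )
        assert report.verdicts["dead"] == "blocked"


class TestSiScan:
    @pytest.fixture()
    def scan(self, si_result):
        return si_result

    def test_all_rows_feasible(self, scan):
        assert (scan.table["status"] == "optimal").all()

    def test_zero_silica_means_zero_biomass(self, scan):
        row0 = scan.table.iloc[0]
        assert row0["biomass"] == pytest.approx(0.0, abs=1e-9)
        assert row0["chrysolaminarin"] > 0

    def test_monotone_tradeoff(self, scan):
        biomass = scan.table["biomass"].to_numpy()
        chryso = scan.table["chrysolaminarin"].to_numpy()
        assert (np.diff(biomass) >= -1e-9).all()
        assert (np.diff(chryso) <= 1e-9).all()

    def test_fixed_carbon_is_partitioned(self, scan, toy_model):
        """All fixed CO2 ends up in biomass carbon or chrysolaminarin."""
        biomass_c = sum(
            -float(c) * toy_model.metabolites[m].formula["C"]
            for m, c in toy_model.reactions["biomass"].stoichiometry.items()
        )
        for _, row in scan.table.iterrows():
            total = biomass_c * row["biomass"] + 6 * row["chrysolaminarin"]
            assert total == pytest.approx(2.05, abs=1e-6)

    def test_zero_co2_zeroes_carbon_fluxes(self, toy_model):
        scan = si_scan(toy_model, [0.0], co2_fix=0.0)
        row = scan.table.iloc[0]
        assert row["status"] == "optimal"
        assert row["biomass"] == pytest.approx(0.0, abs=1e-9)
        assert row["chrysolaminarin"] == pytest.approx(0.0, abs=1e-9)

    def test_si_limitation_lowers_photon_demand(self, scan):
        # silica-starved rows absorb fewer photons than replete rows
        assert scan.table["photon"].iloc[0] < scan.table["photon"].iloc[-1]


class TestAtpmScan:
    @pytest.fixture()
    def scan(self, atpm_result):
        return atpm_result

    def test_photon_non_decreasing(self, scan):
        assert (np.diff(scan.table["photon"].to_numpy()) >= -1e-9).all()

    def test_mito_share_non_decreasing(self, scan):
        ratio = scan.table["mito_to_plastid_atp"].to_numpy()
        assert (np.diff(ratio) >= -1e-9).all()

    def test_cef_inactive_throughout(self, scan):
        assert (scan.table["cef"].abs() <= 1e-9).all()

    def test_valve_flux_increases(self, scan):
        shuttle = scan.table["shuttle_mito"].to_numpy()
        assert shuttle[-1] > shuttle[0]

    def test_o2_production_linear_in_consumption(self, scan, toy_model):
        """Gross O2 evolution rises linearly with mitochondrial O2 use."""
        consumed = 0.5 * scan.table["mito_atp_synthase"].to_numpy()
        produced = scan.table["psii"].to_numpy()  # one O2 per PSII turnover
        slopes = np.diff(produced) / np.diff(consumed)
        assert np.allclose(slopes, slopes[0], atol=1e-6)


class TestShuttleKnockout:
    def test_high_atpm_activates_cef(self, toy_model):
        result = shuttle_knockout_experiment(toy_model, atpm=7.5)
        assert result.wild_type.optimal and result.knockout.optimal
        assert result.wild_type["cef"] == pytest.approx(0.0, abs=1e-9)
        assert result.knockout["cef"] > 1e-6
        assert result.knockout["EX_photon"] > result.wild_type["EX_photon"]

    def test_ko_with_wild_type_photon_is_infeasible(self, toy_model):
        wt = pfba(toy_model, SimulationConstraints(growth=0.024, atpm=7.5))
        pinned = SimulationConstraints(
            growth=0.024, atpm=7.5, fix={"EX_photon": wt["EX_photon"]}
        ).with_knockouts("oaa_mal_mito_tx")
        assert pfba(toy_model, pinned).status == "infeasible"

    def test_ko_of_inactive_reaction_changes_nothing(self, toy_model):
        """Deleting a zero-flux reaction leaves the optimum (and every
        uniquely-determined tracked flux) unchanged."""
        result = shuttle_knockout_experiment(toy_model, atpm=1.5,
                                             knockouts=("arginase_c",))
        assert result.wild_type.total_absolute_flux == pytest.approx(
            result.knockout.total_absolute_flux, rel=1e-9
        )
        # individual tracked fluxes may sit on degenerate alternate optima;
        # the optimum value and the (unique) CEF flux must be unchanged
        assert result.delta.loc["cef", "difference"] == pytest.approx(0.0, abs=1e-9)


class TestMaxYield:
    def test_catalog_loads_and_balances(self, catalog):
        assert set(catalog.modules) == {
            "isobutanol", "phb", "citramalate", "methylsuccinate", "styrene",
            "aminolevulinate", "isoprene", "valencene", "farnesene", "naringenin",
        }

    def test_native_product_yield(self, toy_model):
        res = max_yield(toy_model, "mal_m")
        assert res.status == "optimal"
        assert 0 < res.x <= 0.25
        assert res.v_c == pytest.approx(2.05)

    def test_carbon_ceiling_for_all_catalog_products(self, toy_model, catalog):
        for name in sorted(catalog.modules):
            module = catalog[name]
            res = max_yield(toy_model, module.product_id, catalog_module=module)
            assert res.status == "optimal", name
            assert res.x * res.n_carbon <= 1 + 1e-9, name

    def test_zero_growth_reaches_stoichiometric_ceiling(self, toy_model):
        res = max_yield(toy_model, "mal_m", growth_fraction=0.0)
        assert res.x == pytest.approx(1.0 / res.n_carbon, rel=1e-6)

    @pytest.mark.parametrize("product", ["mal_m", "pyr_c"])
    def test_yield_non_increasing_in_growth_fraction(self, toy_model, product):
        fractions = [0.0, 0.4, 0.8, 1.0]
        yields = [max_yield(toy_model, product, growth_fraction=f).x for f in fractions]
        assert all(a >= b - 1e-9 for a, b in zip(yields, yields[1:]))

    def test_unreachable_product_is_zero_with_diagnostic(self, toy_model):
        res = max_yield(toy_model, "vanillin_c")
        assert res.x == 0.0 and res.status == "unreachable"
        assert "vanillin_c" in res.diagnostic

    def test_catalog_reactions_never_persist(self, toy_model, catalog):
        digest = toy_model.model_hash()
        for name in ("isobutanol", "phb"):
            max_yield(toy_model, catalog[name].product_id, catalog_module=catalog[name])
        assert toy_model.model_hash() == digest

    def test_isobutanol_module_reports_added_genes(self, toy_model, catalog):
        res = max_yield(toy_model, "ibol_c", catalog_module=catalog["isobutanol"])
        assert "kivD" in res.added_genes
        assert len(res.added_reactions) >= 3  # pathway + transport + exchange
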