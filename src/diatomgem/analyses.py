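"""Headline computational experiments on a photoautotroph model.

Four analyses, each a thin layer over :mod:`diatomgem.fba`:

* :func:`essentiality_screen` — single-reaction deletions at fixed growth and
  maintenance; a reaction is essential when pinning its flux to zero makes the
  fixed-growth LP infeasible.
* :func:`si_scan` — silica-limitation sweep: CO₂ and silicic-acid uptake are
  fixed per row, growth is left free, and total flux is minimized; because
  the frustule is the only silica sink, biomass tracks the silica supply and
  surplus carbon overflows into chrysolaminarin export.
* :func:`atpm_scan` — maintenance-energy sweep at fixed growth, tracking the
  photosystems, both ATP synthases, the malate–oxaloacetate shuttle and
  cyclic electron flow.
* :func:`shuttle_knockout_experiment` — paired wild-type vs malate-valve
  knockout simulations at a given maintenance value.
* :func:`max_yield` — maximum theoretical product yield x = v_obj/v_c at a
  fraction of the wild-type growth rate, with temporary export (and, for
  heterologous products, catalog pathway) reactions that never persist on
  the input model.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_BOUND,
    ElementalFormula,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    parse_equation,
)
from .fba import (
    FluxDistribution,
    InfeasibleError,
    SimulationConstraints,
    fba,
    fixed_objective_variability,
    pfba,
)
from .synthetic import DEFAULT_ATPM, DEFAULT_GROWTH_RATE

__all__ = [
    "EssentialityReport",
    "ScanResult",
    "YieldResult",
    "HeterologousCatalog",
    "essentiality_screen",
    "si_scan",
    "atpm_scan",
    "shuttle_knockout_experiment",
    "max_yield",
    "load_default_catalog",
]

ACTIVITY_TOL = 1e-6


# ---------------------------------------------------------------------------
# Reaction essentiality
# ---------------------------------------------------------------------------

@dataclass
class EssentialityReport:
    """Verdict per screened reaction: essential / non-essential / blocked."""

    verdicts: Dict[str, str]
    growth: float
    atpm: Optional[float]

    @property
    def essential(self) -> List[str]:
        return [r for r, v in self.verdicts.items() if v == "essential"]

    @property
    def non_essential(self) -> List[str]:
        return [r for r, v in self.verdicts.items() if v == "non-essential"]

    @property
    def blocked(self) -> List[str]:
        return [r for r, v in self.verdicts.items() if v == "blocked"]

    def totals(self) -> Dict[str, int]:
        out = {"essential": 0, "non-essential": 0, "blocked": 0}
        for v in self.verdicts.values():
            out[v] += 1
        return out

    def by_subsystem(self, model: MetabolicModel) -> pd.DataFrame:
        rows = []
        for rid, verdict in self.verdicts.items():
            rows.append({"subsystem": model.reactions[rid].subsystem or "(none)",
                         "verdict": verdict})
        return (
            pd.DataFrame(rows)
            .groupby(["subsystem", "verdict"])
            .size()
            .unstack(fill_value=0)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"verdict": pd.Series(self.verdicts)}).rename_axis("reaction")


def essentiality_screen(
    model: MetabolicModel,
    constraints: SimulationConstraints,
    reactions: Optional[Sequence[str]] = None,
) -> EssentialityReport:
    """Fix each reaction flux to zero in turn at fixed growth/maintenance.

    Reactions that cannot carry flux at all under the screening environment
    (flux range [0, 0] with the growth and maintenance fixes relaxed) are
    labelled ``blocked`` rather than non-essential, since their deletion is
    vacuous.  Iteration follows the model's reaction order, so results are
    deterministic.
    """
    if constraints.growth is None:
        raise ModelValidationError("essentiality screen requires a fixed growth rate")
    baseline = pfba(model, constraints)
    if not baseline.optimal:
        raise InfeasibleError(
            f"baseline infeasible under the given constraints: {baseline.diagnostic}"
        )
    screened = list(reactions) if reactions is not None else list(model.reactions)
    relaxed = SimulationConstraints(
        exchange_bounds=dict(constraints.exchange_bounds),
        knockouts=constraints.knockouts,
        ratios=constraints.ratios,
    )
    span = fixed_objective_variability(
        model, relaxed, total_flux=float("inf"), reactions=screened
    )
    verdicts: Dict[str, str] = {}
    for rid in screened:
        lo, hi = span.loc[rid, "minimum"], span.loc[rid, "maximum"]
        if abs(lo) <= ACTIVITY_TOL and abs(hi) <= ACTIVITY_TOL:
            verdicts[rid] = "blocked"
            continue
        probe = fba(
            model,
            constraints.with_knockouts(rid),
            objective=model.biomass_reaction_id,
            sense="max",
        )
        verdicts[rid] = "essential" if probe.status != "optimal" else "non-essential"
    return EssentialityReport(verdicts, constraints.growth, constraints.atpm)


# ---------------------------------------------------------------------------
# Parameter scans
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """One row per swept value; infeasible rows carry NaN fluxes."""

    parameter: str
    table: pd.DataFrame

    def __getitem__(self, column: str) -> pd.Series:
        return self.table[column]

    @property
    def feasible(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "optimal"]


def _atp_per_flux(model: MetabolicModel, rxn_id: str) -> float:
    """ATP produced per unit flux (positive coefficients of atp_* species)."""
    total = 0.0
    for mid, coeff in model.reactions[rxn_id].stoichiometry.items():
        if mid.startswith("atp") and coeff > 0:
            total += float(coeff)
    return total


_TRACK_DEFAULT = {
    "psii": "psii",
    "psi": "psi",
    "photon": "EX_photon",
    "plastid_atp_synthase": "atpase_h",
    "mito_atp_synthase": "oxphos_m",
    "shuttle_chlo": "oaa_mal_chlo_tx",
    "shuttle_mito": "oaa_mal_mito_tx",
    "cef": "cef",
    "o2_evolution": "EX_o2",
}


def si_scan(
    model: MetabolicModel,
    si_values: Sequence[float],
    co2_fix: float = 2.05,
    atpm: float = DEFAULT_ATPM,
    si_exchange: str = "EX_sioh4",
    co2_exchange: str = "EX_co2",
    chrysolaminarin_export: str = "EX_chryso",
) -> ScanResult:
    """Sweep silicic-acid uptake at fixed CO₂ supply, minimizing total flux.

    Per row both uptakes are fixed as equalities and growth is free; the
    silica balance then forces the biomass flux while the fixed carbon that
    biomass cannot absorb exits as chrysolaminarin.  Infeasible rows are
    recorded and the scan continues.
    """
    rows = []
    for si in si_values:
        c = SimulationConstraints(
            atpm=atpm, fix={co2_exchange: float(co2_fix), si_exchange: float(si)}
        )
        sol = pfba(model, c)
        row = {"si_uptake": float(si), "status": sol.status}
        if sol.optimal:
            row.update(
                biomass=sol[model.biomass_reaction_id],
                chrysolaminarin=sol[chrysolaminarin_export],
                photon=sol["EX_photon"] if "EX_photon" in sol.fluxes else np.nan,
                o2=sol["EX_o2"] if "EX_o2" in sol.fluxes else np.nan,
            )
        else:
            row.update(biomass=np.nan, chrysolaminarin=np.nan, photon=np.nan, o2=np.nan)
        rows.append(row)
    return ScanResult("si_uptake", pd.DataFrame(rows))


def atpm_scan(
    model: MetabolicModel,
    atpm_values: Optional[Sequence[float]] = None,
    growth: float = DEFAULT_GROWTH_RATE,
    tracked: Optional[Mapping[str, str]] = None,
    constraints: Optional[SimulationConstraints] = None,
) -> ScanResult:
    """Sweep the maintenance-ATP flux at fixed growth (default 0–8, step 0.5).

    Tracked columns report raw fluxes; plastidial and mitochondrial ATP
    synthesis are additionally reported in ATP units (flux × ATP
    stoichiometry) along with their mito:plastid and plastid:mito ratios.
    """
    if atpm_values is None:
        atpm_values = np.arange(0.0, 8.0 + 1e-9, 0.5)
    tracked = dict(tracked or _TRACK_DEFAULT)
    base = constraints or SimulationConstraints()
    rows = []
    for atpm in atpm_values:
        c = SimulationConstraints(
            growth=growth, atpm=float(atpm),
            exchange_bounds=dict(base.exchange_bounds),
            fix=dict(base.fix), knockouts=base.knockouts, ratios=base.ratios,
        )
        sol = pfba(model, c)
        row = {"atpm": float(atpm), "status": sol.status}
        if sol.optimal:
            for label, rid in tracked.items():
                row[label] = sol[rid]
            plastid = sol[tracked["plastid_atp_synthase"]] * _atp_per_flux(
                model, tracked["plastid_atp_synthase"]
            )
            mito = sol[tracked["mito_atp_synthase"]] * _atp_per_flux(
                model, tracked["mito_atp_synthase"]
            )
            row["plastid_atp"] = plastid
            row["mito_atp"] = mito
            row["mito_to_plastid_atp"] = mito / plastid if plastid > 0 else np.inf
            row["plastid_to_mito_atp"] = plastid / mito if mito > 0 else np.inf
        else:
            for label in tracked:
                row[label] = np.nan
        rows.append(row)
    return ScanResult("atpm", pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Malate-valve knockout
# ---------------------------------------------------------------------------

@dataclass
class KnockoutExperiment:
    wild_type: FluxDistribution
    knockout: FluxDistribution
    knocked_out: Tuple[str, ...]
    delta: pd.DataFrame  # tracked fluxes side by side


def shuttle_knockout_experiment(
    model: MetabolicModel,
    atpm: float,
    growth: float = DEFAULT_GROWTH_RATE,
    knockouts: Sequence[str] = ("oaa_mal_mito_tx",),
    tracked: Optional[Mapping[str, str]] = None,
) -> KnockoutExperiment:
    """Wild type vs malate–oxaloacetate valve knockout at one ATPM value.

    The default knockout is the mitochondrial mal/OAA antiporter — the valve's
    obligatory membrane step — whose removal forces the chloroplast to cover
    its ATP deficit by cyclic electron flow at a higher photon cost.
    """
    tracked = dict(tracked or _TRACK_DEFAULT)
    base = SimulationConstraints(growth=growth, atpm=atpm)
    wt = pfba(model, base)
    ko = pfba(model, base.with_knockouts(*knockouts))
    rows = []
    for label, rid in tracked.items():
        rows.append(
            {
                "tracked": label,
                "reaction": rid,
                "wild_type": wt[rid] if wt.optimal else np.nan,
                "knockout": ko[rid] if ko.optimal else np.nan,
            }
        )
    delta = pd.DataFrame(rows).set_index("tracked")
    delta["difference"] = delta["knockout"] - delta["wild_type"]
    return KnockoutExperiment(wt, ko, tuple(knockouts), delta)


# ---------------------------------------------------------------------------
# Heterologous catalog and maximum theoretical yields
# ---------------------------------------------------------------------------

@dataclass
class CatalogModule:
    """A named pathway module: product metabolite plus the reactions to add."""

    name: str
    product_id: str
    reactions: Tuple[Reaction, ...]
    new_metabolites: Tuple[Metabolite, ...]
    gene_labels: Tuple[str, ...]
    notes: str = ""


@dataclass
class HeterologousCatalog:
    """Pathway modules for non-native products, loaded from a TSV listing.

    Every catalog reaction is carbon-balanced (and balanced for N, P and S)
    against the formulae declared in its ``new_metabolites`` column plus the
    host model's formulae; :meth:`validate_against` enforces this at load.
    """

    modules: Dict[str, CatalogModule]

    def __getitem__(self, name: str) -> CatalogModule:
        try:
            return self.modules[name]
        except KeyError:
            raise KeyError(
                f"catalog has no module {name!r}; available: {sorted(self.modules)}"
            ) from None

    def validate_against(self, model: MetabolicModel,
                         elements: Sequence[str] = ("C", "N", "P", "S")) -> None:
        from .qc import check_mass_balance

        for module in self.modules.values():
            work = model.copy()
            for met in module.new_metabolites:
                if met.id not in work.metabolites:
                    work.add_metabolite(met)
            for rxn in module.reactions:
                work.add_reaction(rxn.copy())
            report = check_mass_balance(work, elements)
            bad = {r: imb for r, imb in report.imbalanced.items()
                   if r in {x.id for x in module.reactions}}
            if bad:
                raise ModelValidationError(
                    f"catalog module {module.name!r} is not mass balanced: {bad}"
                )


def load_catalog(path, model: Optional[MetabolicModel] = None) -> HeterologousCatalog:
    """Load a catalog TSV (module, product_id, reaction_id, equation,
    gene_label, ec, new_metabolites)."""
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    modules: Dict[str, CatalogModule] = {}
    for name, group in table.groupby("module", sort=False):
        reactions: List[Reaction] = []
        mets: Dict[str, Metabolite] = {}
        genes: List[str] = []
        for _, row in group.iterrows():
            stoich, reversible = parse_equation(row["equation"])
            reactions.append(
                Reaction(
                    id=row["reaction_id"],
                    name=f"{name} module: {row['gene_label']}",
                    stoichiometry=stoich,
                    lower_bound=-DEFAULT_BOUND if reversible else 0.0,
                    upper_bound=DEFAULT_BOUND,
                    ec_numbers=tuple(e for e in row.get("ec", "").split(";") if e),
                    subsystem=f"heterologous:{name}",
                    gene_association=row["gene_label"].replace(",", " and "),
                )
            )
            genes.append(row["gene_label"])
            for entry in str(row.get("new_metabolites", "")).split(";"):
                entry = entry.strip()
                if not entry:
                    continue
                mid, formula = entry.split("=", 1)
                comp = mid.rsplit("_", 1)[-1]
                mets[mid] = Metabolite(
                    mid, name=mid, compartment=comp,
                    formula=ElementalFormula.parse(formula),
                )
        product = group["product_id"].iloc[0]
        modules[name] = CatalogModule(
            name=name,
            product_id=product,
            reactions=tuple(reactions),
            new_metabolites=tuple(mets.values()),
            gene_labels=tuple(genes),
        )
    catalog = HeterologousCatalog(modules)
    if model is not None:
        catalog.validate_against(model)
    return catalog


def load_default_catalog(model: Optional[MetabolicModel] = None) -> HeterologousCatalog:
    """The catalog shipped with the package (lumped toy-compatible routes)."""
    ref = importlib.resources.files("diatomgem") / "data" / "heterologous_catalog.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_catalog(path, model)


@dataclass
class YieldResult:
    """Maximum theoretical yield of a product.

    ``x = v_obj / v_c`` in mol product per mol carbon-source taken up; the
    carbon ceiling x · n_C ≤ 1 holds for any feasible solution on a CO₂
    carbon source.
    """

    product: str
    v_obj: float
    v_c: float
    x: float
    n_carbon: int
    added_reactions: Tuple[str, ...]
    added_genes: Tuple[str, ...]
    status: str
    diagnostic: str = ""


def max_yield(
    model: MetabolicModel,
    product: str,
    carbon_source: str = "EX_co2",
    growth_fraction: float = 0.8,
    catalog_module: Optional[CatalogModule] = None,
    wild_type_growth: float = DEFAULT_GROWTH_RATE,
    atpm: float = DEFAULT_ATPM,
    carbon_uptake: float = 2.05,
) -> YieldResult:
    """Maximize a product export at a fraction of the wild-type growth rate.

    Growth is fixed to ``growth_fraction × wild_type_growth`` and the carbon
    source uptake to ``carbon_uptake`` (an equality, so v_c is pinned and the
    yield is scale-free); the product's exchange flux is maximized.  Transport
    and exchange reactions for the product — and, when a catalog module is
    given, any missing pathway reactions — are added to a working copy only;
    the input model is never mutated.  An unreachable product yields x = 0
    with a diagnostic rather than an exception.
    """
    work = model.copy()
    added: List[str] = []
    genes: List[str] = []
    if catalog_module is not None:
        for met in catalog_module.new_metabolites:
            if met.id not in work.metabolites:
                work.compartments.setdefault(met.compartment, met.compartment)
                work.add_metabolite(met)
        for rxn in catalog_module.reactions:
            if rxn.id not in work.reactions:
                work.add_reaction(rxn.copy())
                added.append(rxn.id)
        genes.extend(catalog_module.gene_labels)
        if product == catalog_module.product_id or product not in model.metabolites:
            product = catalog_module.product_id
    if product not in work.metabolites:
        return YieldResult(product, 0.0, carbon_uptake, 0.0, 0, tuple(added),
                           tuple(genes), "unreachable",
                           f"metabolite {product!r} not in model or catalog")
    met = work.metabolites[product]
    n_carbon = met.formula["C"]
    if met.compartment != "e":
        ext_id = f"{product.rsplit('_', 1)[0]}_yield_e"
        if ext_id not in work.metabolites:
            work.add_metabolite(Metabolite(ext_id, name=met.name, compartment="e",
                                           formula=met.formula))
        tx_id = f"__yield_tx_{product}"
        work.add_reaction(Reaction(id=tx_id, kind="transport",
                                   stoichiometry={product: Fraction(-1), ext_id: Fraction(1)},
                                   lower_bound=0.0, upper_bound=DEFAULT_BOUND))
        added.append(tx_id)
        drain_target = ext_id
    else:
        drain_target = product
    ex_id = f"__yield_ex_{product}"
    work.add_reaction(Reaction(id=ex_id, kind="exchange",
                               stoichiometry={drain_target: Fraction(-1)},
                               lower_bound=0.0, upper_bound=DEFAULT_BOUND))
    added.append(ex_id)
    constraints = SimulationConstraints(
        growth=growth_fraction * wild_type_growth,
        atpm=atpm,
        fix={carbon_source: carbon_uptake},
    )
    sol = fba(work, constraints, objective=ex_id, sense="max")
    if not sol.optimal:
        return YieldResult(product, 0.0, carbon_uptake, 0.0, n_carbon, tuple(added),
                           tuple(genes), sol.status, sol.diagnostic)
    v_obj = sol.objective_value
    v_c = sol[carbon_source]
    x = v_obj / v_c if v_c else 0.0
    if n_carbon and x * n_carbon > 1 + 1e-6:
        raise ModelValidationError(
            f"carbon ceiling violated for {product}: x·nC = {x * n_carbon:.6f} > 1"
        )
    return YieldResult(product, v_obj, v_c, x, n_carbon, tuple(added), tuple(genes),
                       "optimal")
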