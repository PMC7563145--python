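"""Model comparison by EC number, carbon partitioning and flux summaries.

Two reconstructions of related organisms can be compared on enzymatic content
by intersecting their Enzyme Commission annotations; a solved flux
distribution can be summarised per pathway (active reaction counts, total
absolute flux, named pathway activity flags) and dissected at a branch-point
metabolite into per-consumer carbon-flux percentages.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .core import MetabolicModel, ModelValidationError, normalize_ec
from .fba import FluxDistribution

__all__ = [
    "ComparisonReport",
    "CarbonPartition",
    "CategoryMap",
    "ec_compare",
    "carbon_partition",
    "flux_summary",
    "load_category_map",
    "load_default_category_map",
]

ACTIVITY_TOL = 1e-6


# ---------------------------------------------------------------------------
# Category map
# ---------------------------------------------------------------------------

@dataclass
class CategoryMap:
    """Maps a reaction (via subsystem, else EC prefix) to a pathway category."""

    subsystem_rules: Dict[str, str] = field(default_factory=dict)
    ec_prefix_rules: Tuple[Tuple[str, str], ...] = ()

    def category_for(self, subsystem: str, ec_numbers: Sequence[str]) -> Optional[str]:
        rule = self.subsystem_rules.get(subsystem.strip().lower())
        if rule:
            return rule
        best: Tuple[int, Optional[str]] = (0, None)
        for prefix, category in self.ec_prefix_rules:
            for ec in ec_numbers:
                if ec.startswith(prefix) and len(prefix) > best[0]:
                    best = (len(prefix), category)
        return best[1]


def load_category_map(path) -> CategoryMap:
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    subsystem_rules: Dict[str, str] = {}
    ec_rules: List[Tuple[str, str]] = []
    for _, row in table.iterrows():
        if row["key_type"] == "subsystem":
            subsystem_rules[row["key"].strip().lower()] = row["category"]
        elif row["key_type"] == "ec_prefix":
            ec_rules.append((row["key"], row["category"]))
        else:
            raise ModelValidationError(f"unknown key_type {row['key_type']!r}")
    return CategoryMap(subsystem_rules, tuple(ec_rules))


def load_default_category_map() -> CategoryMap:
    ref = importlib.resources.files("diatomgem") / "data" / "ec_categories.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_category_map(path)


# ---------------------------------------------------------------------------
# EC comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Set algebra over full four-field EC annotations of two models."""

    common: frozenset
    unique_a: frozenset
    unique_b: frozenset
    partial_a: frozenset
    partial_b: frozenset
    category_tallies: pd.DataFrame

    def counts(self) -> Dict[str, int]:
        return {
            "common": len(self.common),
            "unique_a": len(self.unique_a),
            "unique_b": len(self.unique_b),
            "partial_a": len(self.partial_a),
            "partial_b": len(self.partial_b),
        }


def _ec_sets(model: MetabolicModel) -> Tuple[set, set, Dict[str, set]]:
    full: set = set()
    partial: set = set()
    by_ec: Dict[str, set] = {}
    for rxn in model.reactions.values():
        for ec in rxn.ec_numbers:
            norm, is_partial = normalize_ec(ec)
            (partial if is_partial else full).add(norm)
            by_ec.setdefault(norm, set()).add(rxn.id)
    return full, partial, by_ec


def ec_compare(
    model_a: MetabolicModel,
    model_b: MetabolicModel,
    category_map: Optional[CategoryMap] = None,
) -> ComparisonReport:
    """Common/unique enzyme sets between two models on exact 4-field ECs.

    Partial ECs (any ``-`` field) are excluded from the set algebra and
    counted separately.  Category tallies classify each full EC through the
    subsystems/ECs of the reactions carrying it.
    """
    full_a, partial_a, by_a = _ec_sets(model_a)
    full_b, partial_b, by_b = _ec_sets(model_b)
    if not (full_a or partial_a):
        raise ModelValidationError(f"model {model_a.id!r} carries no EC annotations")
    if not (full_b or partial_b):
        raise ModelValidationError(f"model {model_b.id!r} carries no EC annotations")
    common = frozenset(full_a & full_b)
    unique_a = frozenset(full_a - full_b)
    unique_b = frozenset(full_b - full_a)

    cmap = category_map or load_default_category_map()

    def classify(ec: str, model: MetabolicModel, by_ec: Mapping[str, set]) -> str:
        for rid in sorted(by_ec.get(ec, ())):
            rxn = model.reactions[rid]
            cat = cmap.category_for(rxn.subsystem, rxn.ec_numbers)
            if cat:
                return cat
        return "(uncategorized)"

    rows: Dict[str, Dict[str, int]] = {}
    for ec in common:
        cat = classify(ec, model_a, by_a)
        rows.setdefault(cat, {"common": 0, "unique_a": 0, "unique_b": 0})["common"] += 1
    for ec in unique_a:
        cat = classify(ec, model_a, by_a)
        rows.setdefault(cat, {"common": 0, "unique_a": 0, "unique_b": 0})["unique_a"] += 1
    for ec in unique_b:
        cat = classify(ec, model_b, by_b)
        rows.setdefault(cat, {"common": 0, "unique_a": 0, "unique_b": 0})["unique_b"] += 1
    tallies = (
        pd.DataFrame.from_dict(rows, orient="index")
        .sort_index()
        .rename_axis("category")
        if rows
        else pd.DataFrame(columns=["common", "unique_a", "unique_b"])
    )
    return ComparisonReport(common, unique_a, unique_b,
                            frozenset(partial_a), frozenset(partial_b), tallies)


# ---------------------------------------------------------------------------
# Carbon partition at a branch metabolite
# ---------------------------------------------------------------------------

@dataclass
class CarbonPartition:
    """Per-consumer carbon-flux percentage at a branch metabolite (sums to 100)."""

    metabolite: str
    fractions: Dict[str, float]  # reaction id -> percent

    def to_series(self) -> pd.Series:
        return pd.Series(self.fractions, name=f"%C into consumers of {self.metabolite}")


def carbon_partition(
    flux: FluxDistribution,
    model: MetabolicModel,
    branch_metabolite: str,
) -> CarbonPartition:
    """Fraction of carbon flux taken by each consumer of a branch metabolite.

    fraction_r = C-weighted consumption flux of r ÷ total C-weighted
    consumption × 100, where consumption of metabolite m by reaction r is
    max(−coeff_r(m)·v_r, 0).
    """
    if branch_metabolite not in model.metabolites:
        raise ModelValidationError(f"unknown metabolite {branch_metabolite!r}")
    met = model.metabolites[branch_metabolite]
    if met.formula.unknown:
        raise ModelValidationError(
            f"metabolite {branch_metabolite!r} has no formula; cannot weight by carbon"
        )
    n_c = met.formula["C"]
    consumption: Dict[str, float] = {}
    for rid, rxn in model.reactions.items():
        coeff = rxn.stoichiometry.get(branch_metabolite)
        if coeff is None or rid not in flux.fluxes:
            continue
        rate = -float(coeff) * flux.fluxes[rid]
        if rate > ACTIVITY_TOL:
            consumption[rid] = rate * n_c
    total = sum(consumption.values())
    if total <= 0:
        raise ModelValidationError(
            f"no consuming flux at {branch_metabolite!r}; partition undefined"
        )
    return CarbonPartition(
        branch_metabolite,
        {rid: 100.0 * v / total for rid, v in sorted(consumption.items())},
    )


# ---------------------------------------------------------------------------
# Flux summary
# ---------------------------------------------------------------------------

def flux_summary(
    flux: FluxDistribution,
    model: MetabolicModel,
    roles: Optional[Mapping[str, str]] = None,
) -> Tuple[pd.DataFrame, Dict[str, bool]]:
    """Per-subsystem activity table plus named pathway flags.

    The table reports, per subsystem, the number of reactions with
    |v| > 1e-6 and the summed absolute flux.  ``roles`` (e.g. the toy-model
    manifest roles) produce a ``role → active`` flag map, so headline
    qualitative statements (LEF active, CEF inactive, arginase silent) can be
    asserted by name.
    """
    rows = []
    for rid, rxn in model.reactions.items():
        v = flux.fluxes.get(rid, 0.0)
        rows.append(
            {
                "subsystem": rxn.subsystem or "(none)",
                "active": abs(v) > ACTIVITY_TOL,
                "abs_flux": abs(v),
            }
        )
    table = (
        pd.DataFrame(rows)
        .groupby("subsystem")
        .agg(active_reactions=("active", "sum"), total_abs_flux=("abs_flux", "sum"))
        .sort_index()
    )
    flags: Dict[str, bool] = {}
    for role, rid in (roles or {}).items():
        flags[role] = abs(flux.fluxes.get(rid, 0.0)) > ACTIVITY_TOL
    return table, flags
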