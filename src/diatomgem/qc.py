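"""Model-quality checks: elemental balance, energy leaks, and network gaps.

These are the curation checks performed while refining a reconstruction:

* :func:`check_mass_balance` — per-reaction elemental imbalance for a chosen
  element set (carbon, nitrogen, phosphorus, sulfur by default, plus silicon
  for diatom models).  Exchange, biomass and maintenance pseudo-reactions are
  intrinsically unbalanced and are skipped by kind; reactions touching a
  metabolite of unknown formula are skipped with a reason.
* :func:`leak_test` — with every exchange closed, no energy carrier may be
  regenerated: the maximal flux through a probe drain (ATP → ADP + Pi,
  NADH → NAD⁺, NADPH → NADP⁺) must be zero, otherwise the network contains a
  thermodynamically infeasible cycle.
* :func:`find_gaps` / :func:`gap_fill` — producibility of biomass precursors
  one by one through temporary sink reactions, and exhaustive small-subset
  search for reactions restoring producibility of a gapped metabolite.

Proton and charge balance are deliberately not enforced; hydrogen imbalances
are reported informationally when ``"H"`` is included in the element list.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .core import MetabolicModel, ModelValidationError, Reaction
from .fba import FluxDistribution, SimulationConstraints, fba

__all__ = [
    "BalanceReport",
    "GapReport",
    "check_mass_balance",
    "leak_test",
    "find_gaps",
    "gap_fill",
    "biomass_precursors",
    "DEFAULT_ELEMENTS",
    "PRODUCIBILITY_TOL",
]

#: Currency metabolites (by base name) excluded from precursor producibility:
#: they appear in the biomass drain only as a cofactor couple (GAM ATP
#: hydrolysis, condensation water), not as material drawn into biomass.
CURRENCY_BASES = frozenset({"atp", "adp", "h2o", "pi", "nad", "nadh", "nadp", "nadph"})


def biomass_precursors(model: MetabolicModel) -> List[str]:
    """Metabolites consumed by the biomass reaction, minus currency couples."""
    if model.biomass_reaction_id is None:
        raise ModelValidationError("model declares no biomass reaction")
    rxn = model.reactions[model.biomass_reaction_id]
    out = []
    for mid, coeff in rxn.stoichiometry.items():
        if coeff >= 0:
            continue
        base = mid.rsplit("_", 1)[0].lower()
        if base not in CURRENCY_BASES:
            out.append(mid)
    return out

DEFAULT_ELEMENTS = ("C", "N", "P", "S", "Si")
PRODUCIBILITY_TOL = 1e-9


@dataclass
class BalanceReport:
    """Partition of the reaction set into balanced / imbalanced / skipped."""

    elements: Tuple[str, ...]
    balanced: List[str]
    imbalanced: Dict[str, Dict[str, Fraction]]  # rxn -> element -> signed excess
    skipped: Dict[str, str]  # rxn -> reason

    @property
    def ok(self) -> bool:
        return not self.imbalanced

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rid in self.balanced:
            rows.append({"reaction": rid, "status": "balanced", "detail": ""})
        for rid, imb in self.imbalanced.items():
            detail = ";".join(f"{el}:{val:+}" for el, val in sorted(imb.items()))
            rows.append({"reaction": rid, "status": "imbalanced", "detail": detail})
        for rid, reason in self.skipped.items():
            rows.append({"reaction": rid, "status": "skipped", "detail": reason})
        return pd.DataFrame(rows, columns=["reaction", "status", "detail"])


def check_mass_balance(
    model: MetabolicModel, elements: Sequence[str] = DEFAULT_ELEMENTS
) -> BalanceReport:
    """Check Σ coeff(m)·formula(m)[e] = 0 per reaction for each element."""
    model.validate()
    balanced: List[str] = []
    imbalanced: Dict[str, Dict[str, Fraction]] = {}
    skipped: Dict[str, str] = {}
    for rid, rxn in model.reactions.items():
        if rxn.kind in ("exchange", "biomass", "maintenance"):
            skipped[rid] = f"kind:{rxn.kind}"
            continue
        unknown = [m for m in rxn.stoichiometry if model.metabolites[m].formula.unknown]
        if unknown:
            skipped[rid] = "unknown formula: " + ",".join(sorted(unknown))
            continue
        excess: Dict[str, Fraction] = {}
        for element in elements:
            total = Fraction(0)
            for mid, coeff in rxn.stoichiometry.items():
                total += coeff * model.metabolites[mid].formula[element]
            if total != 0:
                excess[element] = total
        if excess:
            imbalanced[rid] = excess
        else:
            balanced.append(rid)
    return BalanceReport(tuple(elements), balanced, imbalanced, skipped)


# ---------------------------------------------------------------------------
# Energy-leak probes
# ---------------------------------------------------------------------------

#: Probe drains tried per compartment when present: (name, consumed, produced).
_PROBE_COUPLES = [
    ("ATP", ("atp", "h2o"), ("adp", "pi")),
    ("NADH", ("nadh",), ("nad",)),
    ("NADPH", ("nadph",), ("nadp",)),
]


def _default_probes(model: MetabolicModel) -> Dict[str, Dict[str, int]]:
    probes: Dict[str, Dict[str, int]] = {}
    comps = {m.compartment for m in model.metabolites.values()}
    for comp in sorted(comps):
        for name, consumed, produced in _PROBE_COUPLES:
            stoich = {}
            ok = True
            for base in consumed:
                mid = f"{base}_{comp}"
                if mid not in model.metabolites:
                    ok = False
                    break
                stoich[mid] = stoich.get(mid, 0) - 1
            for base in produced:
                mid = f"{base}_{comp}"
                if mid not in model.metabolites:
                    ok = False
                    break
                stoich[mid] = stoich.get(mid, 0) + 1
            if ok:
                probes[f"{name}_{comp}"] = stoich
    return probes


def leak_test(
    model: MetabolicModel,
    targets: Optional[Mapping[str, Mapping[str, int]]] = None,
) -> pd.Series:
    """Maximal probe-drain flux with all exchanges closed; 0 means leak-free.

    ``targets`` maps a probe name to a drain stoichiometry; by default an
    ATP-, NADH- and NADPH-regeneration probe is constructed for every
    compartment that carries the couple.  An unbounded LP is reported as
    ``inf`` (a leak with no finite ceiling).
    """
    model.validate()
    targets = dict(targets) if targets is not None else _default_probes(model)
    results: Dict[str, float] = {}
    work = model.copy()
    closed = {rid: (0.0, 0.0) for rid in work.exchanges()}
    for name, stoich in targets.items():
        probe_id = f"__probe_{name}"
        work.add_reaction(
            Reaction(id=probe_id, stoichiometry={m: Fraction(c) for m, c in stoich.items()},
                     lower_bound=0.0, upper_bound=float("inf"), kind="metabolic")
        )
        sol = fba(work, SimulationConstraints(exchange_bounds=closed),
                  objective=probe_id, sense="max")
        if sol.status == "unbounded":
            results[name] = float("inf")
        elif sol.status == "optimal":
            results[name] = sol.objective_value
        else:  # infeasible cannot happen (0 is always feasible) but be explicit
            results[name] = float("nan")
        work.remove_reaction(probe_id)
    return pd.Series(results, name="max_leak_flux")


# ---------------------------------------------------------------------------
# Gap finding and filling
# ---------------------------------------------------------------------------

@dataclass
class GapReport:
    """Per-precursor producibility; gapped ⇔ max production ≤ tolerance."""

    production: Dict[str, float]
    gapped: List[str]
    tolerance: float = PRODUCIBILITY_TOL
    fills: Dict[str, List[Tuple[str, ...]]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.gapped

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "max_production": pd.Series(self.production),
                "gapped": pd.Series({m: m in self.gapped for m in self.production}),
            }
        ).rename_axis("metabolite")


def _max_production(
    model: MetabolicModel,
    metabolite_id: str,
    constraints: SimulationConstraints,
) -> float:
    work = model.copy()
    sink_id = f"__sink_{metabolite_id}"
    work.add_reaction(
        Reaction(id=sink_id, stoichiometry={metabolite_id: Fraction(-1)},
                 lower_bound=0.0, upper_bound=DEFAULT_SINK_BOUND, kind="metabolic")
    )
    sol = fba(work, constraints, objective=sink_id, sense="max")
    return sol.objective_value if sol.optimal else 0.0


DEFAULT_SINK_BOUND = 1000.0


def find_gaps(
    model: MetabolicModel,
    precursors: Sequence[str],
    nutrient_exchanges: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> GapReport:
    """Maximize a temporary sink for each precursor; gapped if optimum ≈ 0.

    ``nutrient_exchanges`` overrides exchange bounds (default: the model's own
    bounds, i.e. whatever medium the model declares).  The temporary sink is
    added to a working copy, so the input model is never mutated.
    """
    model.validate()
    for mid in precursors:
        if mid not in model.metabolites:
            raise ModelValidationError(f"unknown precursor metabolite {mid!r}")
    constraints = SimulationConstraints(
        exchange_bounds=dict(nutrient_exchanges or {})
    )
    production: Dict[str, float] = {}
    gapped: List[str] = []
    for mid in precursors:
        flux = _max_production(model, mid, constraints)
        production[mid] = flux
        if flux <= PRODUCIBILITY_TOL:
            gapped.append(mid)
    return GapReport(production, gapped)


def gap_fill(
    model: MetabolicModel,
    gapped: str,
    pool: Sequence[Reaction],
    max_additions: int = 3,
    nutrient_exchanges: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> List[Tuple[str, ...]]:
    """Exhaustively search pool subsets restoring producibility of a metabolite.

    All minimal subsets (of the smallest size that works, up to
    ``max_additions``) are returned in deterministic lexicographic order of
    reaction ids.  An empty list means no subset restores producibility.
    """
    if gapped not in model.metabolites:
        raise ModelValidationError(f"unknown precursor metabolite {gapped!r}")
    if max_additions < 1:
        raise ModelValidationError("max_additions must be ≥ 1")
    constraints = SimulationConstraints(exchange_bounds=dict(nutrient_exchanges or {}))
    by_id = {r.id: r for r in pool}
    ordered = sorted(by_id)
    solutions: List[Tuple[str, ...]] = []
    for size in range(1, min(max_additions, len(ordered)) + 1):
        for combo in itertools.combinations(ordered, size):
            work = model.copy()
            new_mets = []
            for rid in combo:
                rxn = by_id[rid].copy()
                for mid in rxn.stoichiometry:
                    if mid not in work.metabolites:
                        raise ModelValidationError(
                            f"candidate {rid!r} references unknown metabolite {mid!r}"
                        )
                work.add_reaction(rxn)
            if _max_production(work, gapped, constraints) > PRODUCIBILITY_TOL:
                solutions.append(combo)
        if solutions:
            break  # minimal size reached; do not search larger subsets
    return solutions
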