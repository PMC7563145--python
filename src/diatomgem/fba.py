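"""Flux balance analysis: LP assembly, plain FBA and total-flux minimization.

The steady-state constraint is S·v = 0 with per-reaction flux bounds.  Two
objectives are supported:

* :func:`fba` — maximize or minimize a linear combination of fluxes
  (typically a single reaction such as the biomass drain or a product
  exchange);
* :func:`pfba` — minimize the total absolute flux Σ|v_i| subject to a fixed
  growth rate and a fixed ATP-maintenance flux.  Each (potentially
  reversible) flux is split into non-negative forward and reverse components,
  giving an ordinary LP whose optimum equals the minimal Σ|v|.

All problems are solved with scipy's HiGHS interior/simplex implementation,
which is deterministic, so the returned vertex is reproducible.  pFBA optima
may still be degenerate in the flux space; :func:`fixed_objective_variability`
computes per-reaction flux ranges at the pFBA optimum so that point estimates
can be certified unique (range width ≤ 1e-6) before being reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .core import MetabolicModel, ModelValidationError, stoichiometric_matrix

__all__ = [
    "SimulationConstraints",
    "FluxDistribution",
    "InfeasibleError",
    "fba",
    "pfba",
    "fixed_objective_variability",
]

FEASIBILITY_TOL = 1e-9
FLUX_ROUND = 1e-6  # reported fluxes smaller than this are rounded to zero


class InfeasibleError(RuntimeError):
    """Raised by callers that require an optimal solution."""


@dataclass
class SimulationConstraints:
    """Environmental and experimental constraints layered onto a model.

    Parameters
    ----------
    growth:
        Fixed growth rate t in h⁻¹, applied as an equality on the biomass
        reaction flux (v_biomass = t).
    atpm:
        Fixed non-growth ATP maintenance in mmol/(gDCW·h), applied as an
        equality on the maintenance reaction.
    exchange_bounds:
        Overrides of (lower, upper) bounds for named exchange reactions.
    fix:
        Arbitrary reaction-id → value equality fixes.
    knockouts:
        Reactions whose flux is pinned to zero.
    ratios:
        ``(rxn_a, rxn_b, k)`` triples enforcing v_a − k·v_b = 0 with k > 0,
        e.g. a fixed PSII:PSI photon-use ratio.
    """

    growth: Optional[float] = None
    atpm: Optional[float] = None
    exchange_bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    fix: Dict[str, float] = field(default_factory=dict)
    knockouts: frozenset = frozenset()
    ratios: Tuple[Tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        self.knockouts = frozenset(self.knockouts)
        for a, b, k in self.ratios:
            if k <= 0:
                raise ModelValidationError(f"ratio constraint {a}:{b} needs k > 0, got {k}")

    def with_knockouts(self, *rxn_ids: str) -> "SimulationConstraints":
        return SimulationConstraints(
            growth=self.growth,
            atpm=self.atpm,
            exchange_bounds=dict(self.exchange_bounds),
            fix=dict(self.fix),
            knockouts=self.knockouts | set(rxn_ids),
            ratios=self.ratios,
        )

    def with_fix(self, **fixes: float) -> "SimulationConstraints":
        merged = dict(self.fix)
        merged.update(fixes)
        return SimulationConstraints(
            growth=self.growth,
            atpm=self.atpm,
            exchange_bounds=dict(self.exchange_bounds),
            fix=merged,
            knockouts=self.knockouts,
            ratios=self.ratios,
        )


@dataclass
class FluxDistribution:
    """A steady-state flux vector plus solver metadata."""

    fluxes: Dict[str, float]
    objective_value: Optional[float]
    status: str  # optimal | infeasible | unbounded
    total_absolute_flux: Optional[float] = None
    diagnostic: str = ""

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def to_series(self) -> pd.Series:
        return pd.Series(self.fluxes, name="flux")


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------

def _effective_bounds(
    model: MetabolicModel, constraints: SimulationConstraints
) -> Dict[str, Tuple[float, float]]:
    bounds: Dict[str, Tuple[float, float]] = {
        rid: (r.lower_bound, r.upper_bound) for rid, r in model.reactions.items()
    }
    for rid, (lb, ub) in constraints.exchange_bounds.items():
        _require(model, rid)
        bounds[rid] = (lb, ub)
    fixes = dict(constraints.fix)
    if constraints.growth is not None:
        if model.biomass_reaction_id is None:
            raise ModelValidationError("model has no biomass reaction to fix growth on")
        fixes[model.biomass_reaction_id] = constraints.growth
    if constraints.atpm is not None:
        if model.atpm_reaction_id is None:
            raise ModelValidationError("model has no ATP-maintenance reaction")
        fixes[model.atpm_reaction_id] = constraints.atpm
    # fixes and knockouts intersect (a knockout cannot relax a growth fix:
    # deleting the biomass reaction at fixed growth is infeasible, not vacuous)
    for rid, value in fixes.items():
        _require(model, rid)
        lo, hi = bounds[rid]
        bounds[rid] = (max(lo, value), min(hi, value))
    for rid in constraints.knockouts:
        _require(model, rid)
        lo, hi = bounds[rid]
        bounds[rid] = (max(lo, 0.0), min(hi, 0.0))
    return bounds


def _require(model: MetabolicModel, rid: str) -> None:
    if rid not in model.reactions:
        raise ModelValidationError(f"constraint references unknown reaction {rid!r}")


@dataclass
class _Problem:
    S: sparse.csr_matrix  # equality rows: metabolites + ratio constraints
    lb: np.ndarray
    ub: np.ndarray
    rxn_ids: List[str]
    rxn_index: Dict[str, int]


def _assemble(model: MetabolicModel, constraints: SimulationConstraints) -> _Problem:
    sm = stoichiometric_matrix(model)
    bounds = _effective_bounds(model, constraints)
    rxn_ids = list(model.reactions)
    n = len(rxn_ids)
    rows = [sm.matrix]
    for a, b, k in constraints.ratios:
        _require(model, a)
        _require(model, b)
        row = sparse.csr_matrix(
            ([1.0, -float(k)], ([0, 0], [sm.reaction_index[a], sm.reaction_index[b]])),
            shape=(1, n),
        )
        rows.append(row)
    S = sparse.vstack(rows).tocsr() if len(rows) > 1 else sm.matrix
    lb = np.array([bounds[r][0] for r in rxn_ids], dtype=float)
    ub = np.array([bounds[r][1] for r in rxn_ids], dtype=float)
    if np.any(lb > ub):
        bad = [rxn_ids[i] for i in np.nonzero(lb > ub)[0]]
        raise _TriviallyInfeasible(f"contradictory bounds on {bad}")
    return _Problem(S, lb, ub, rxn_ids, sm.reaction_index)


class _TriviallyInfeasible(Exception):
    """Constraint intersection is empty before any LP is solved."""


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _solve(c, A_eq, b_eq, lb, ub, A_ub=None, b_ub=None):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL,
                 "dual_feasibility_tolerance": FEASIBILITY_TOL},
    )
    return res, _STATUS.get(res.status, "numerical")


def _clean(x: np.ndarray) -> np.ndarray:
    out = np.asarray(x, dtype=float).copy()
    out[np.abs(out) < FLUX_ROUND] = 0.0
    return out


# ---------------------------------------------------------------------------
# Public solvers
# ---------------------------------------------------------------------------

def fba(
    model: MetabolicModel,
    constraints: Optional[SimulationConstraints] = None,
    objective: Mapping[str, float] | str = "",
    sense: str = "max",
) -> FluxDistribution:
    """Plain FBA: optimize a flux (or weighted combination c·v).

    ``objective`` may be a reaction id or a ``{reaction_id: weight}`` map;
    ``sense`` is ``"max"`` or ``"min"``.  Infeasibility or unboundedness is
    reported in ``status``, never silently.
    """
    constraints = constraints or SimulationConstraints()
    try:
        prob = _assemble(model, constraints)
    except _TriviallyInfeasible as exc:
        return FluxDistribution({}, None, "infeasible", diagnostic=str(exc))
    if isinstance(objective, str):
        if not objective:
            raise ModelValidationError("objective reaction id is empty")
        objective = {objective: 1.0}
    c = np.zeros(len(prob.rxn_ids))
    for rid, w in objective.items():
        _require(model, rid)
        c[prob.rxn_index[rid]] = w
    if sense not in ("max", "min"):
        raise ModelValidationError(f"sense must be max or min, got {sense!r}")
    sign = -1.0 if sense == "max" else 1.0
    res, status = _solve(sign * c, prob.S, np.zeros(prob.S.shape[0]), prob.lb, prob.ub)
    if status != "optimal":
        return FluxDistribution({}, None, status, diagnostic=res.message)
    v = _clean(res.x)
    return FluxDistribution(
        fluxes=dict(zip(prob.rxn_ids, v)),
        objective_value=float(c @ res.x),
        status="optimal",
        total_absolute_flux=float(np.abs(res.x).sum()),
    )


def _split_problem(prob: _Problem):
    """Forward/reverse split: v = p − q with p, q ≥ 0."""
    n = len(prob.rxn_ids)
    lb_p = np.maximum(prob.lb, 0.0)
    ub_p = np.maximum(prob.ub, 0.0)
    lb_q = np.maximum(-prob.ub, 0.0)
    ub_q = np.maximum(-prob.lb, 0.0)
    A = sparse.hstack([prob.S, -prob.S]).tocsr()
    lb = np.concatenate([lb_p, lb_q])
    ub = np.concatenate([ub_p, ub_q])
    return A, lb, ub, n


def pfba(
    model: MetabolicModel,
    constraints: Optional[SimulationConstraints] = None,
) -> FluxDistribution:
    """Minimize total absolute flux Σ|v_i| under the given constraints.

    The paper-style simulation fixes the growth rate and the ATP-maintenance
    flux through ``constraints`` and leaves nutrient exchanges free; the
    minimal-total-flux distribution is then the predicted metabolic state.
    """
    constraints = constraints or SimulationConstraints()
    try:
        prob = _assemble(model, constraints)
    except _TriviallyInfeasible as exc:
        binding = _binding_fixes(model, constraints)
        return FluxDistribution({}, None, "infeasible",
                                diagnostic=f"{exc} (fixed fluxes: {binding})")
    A, lb, ub, n = _split_problem(prob)
    c = np.ones(2 * n)
    res, status = _solve(c, A, np.zeros(A.shape[0]), lb, ub)
    if status != "optimal":
        binding = _binding_fixes(model, constraints)
        return FluxDistribution(
            {}, None, status,
            diagnostic=f"{res.message} (fixed fluxes: {binding})",
        )
    v = _clean(res.x[:n] - res.x[n:])
    return FluxDistribution(
        fluxes=dict(zip(prob.rxn_ids, v)),
        objective_value=float(res.fun),
        status="optimal",
        total_absolute_flux=float(res.fun),
    )


def _binding_fixes(model, constraints) -> Dict[str, float]:
    out: Dict[str, float] = dict(constraints.fix)
    if constraints.growth is not None and model.biomass_reaction_id:
        out[model.biomass_reaction_id] = constraints.growth
    if constraints.atpm is not None and model.atpm_reaction_id:
        out[model.atpm_reaction_id] = constraints.atpm
    return out


def fixed_objective_variability(
    model: MetabolicModel,
    constraints: Optional[SimulationConstraints],
    total_flux: float,
    reactions: Sequence[str],
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Per-reaction [min, max] flux over all pFBA-optimal distributions.

    The total absolute flux is constrained to the previously found optimum
    (within ``tol``); a width ≤ 1e-6 certifies that the reported point flux is
    uniquely determined despite possible LP degeneracy.
    """
    constraints = constraints or SimulationConstraints()
    prob = _assemble(model, constraints)
    A, lb, ub, n = _split_problem(prob)
    if np.isfinite(total_flux):
        A_ub = sparse.csr_matrix(np.ones((1, 2 * n)))
        b_ub = np.array([total_flux + tol])
    else:  # plain FVA: no total-flux cap
        A_ub, b_ub = None, None
    rows = []
    for rid in reactions:
        _require(model, rid)
        j = prob.rxn_index[rid]
        c = np.zeros(2 * n)
        c[j], c[n + j] = 1.0, -1.0
        lo_res, lo_status = _solve(c, A, np.zeros(A.shape[0]), lb, ub, A_ub, b_ub)
        hi_res, hi_status = _solve(-c, A, np.zeros(A.shape[0]), lb, ub, A_ub, b_ub)
        if lo_status != "optimal" or hi_status != "optimal":
            raise InfeasibleError(
                f"variability LP for {rid} returned {lo_status}/{hi_status}"
            )
        lo = float(lo_res.x[j] - lo_res.x[n + j])
        hi = float(hi_res.x[j] - hi_res.x[n + j])
        rows.append((rid, lo, hi, hi - lo))
    return pd.DataFrame(rows, columns=["reaction", "minimum", "maximum", "width"]).set_index(
        "reaction"
    )
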