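"""Domain types and I/O for compartmentalized metabolic models.

A :class:`MetabolicModel` is a stoichiometric reconstruction: metabolites with
elemental formulae, reactions with rational stoichiometric coefficients and
flux bounds in mmol/(gDCW·h), gene associations and EC annotations, organised
into compartments.  The module provides readers/writers for three dialects
(native JSON, SBML Level 3 with the ``fbc`` package, and a flat TSV reaction
listing) plus assembly of the sparse stoichiometric matrix S used by flux
balance analysis, where steady state imposes S·v = 0.

Conventions
-----------
* Compartment codes: ``c`` cytosol, ``h`` chloroplast, ``m`` mitochondrion,
  ``e`` external; metabolite ids are suffixed ``_<code>``.
* Exchange reactions are written as single-participant supply/drain columns
  ("external → internal" orientation), so uptake is a positive flux.
* Unbounded reactions default to ±1000 (reversible) or [0, 1000]
  (irreversible) mmol/(gDCW·h).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "DEFAULT_BOUND",
    "ElementalFormula",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "StoichMatrix",
    "ModelValidationError",
    "ModelParseError",
    "read_model",
    "write_model",
    "stoichiometric_matrix",
    "compartment_census",
    "normalize_ec",
]

DEFAULT_BOUND = 1000.0

#: Monoisotopic-free average atomic masses (g/mol) for mass bookkeeping.
ATOMIC_MASSES: Dict[str, float] = {
    "C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Si": 28.085, "Mg": 24.305, "Fe": 55.845, "Cu": 63.546,
    "K": 39.098, "Na": 22.990, "Ca": 40.078, "Cl": 35.45, "Zn": 65.38,
}

REACTION_KINDS = ("metabolic", "transport", "exchange", "biomass", "maintenance")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed; names the offending element."""


# ---------------------------------------------------------------------------
# Elemental formulae
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementalFormula:
    """Element → count map; ``unknown`` marks metabolites without a formula.

    Counts are non-negative integers.  An unknown formula takes part in no
    balance check but is reported by :func:`diatomgem.qc.check_mass_balance`.
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    unknown: bool = False

    def __post_init__(self) -> None:
        clean = {}
        for element, count in dict(self.counts).items():
            if count < 0:
                raise ModelValidationError(
                    f"negative count for element {element!r}: {count}"
                )
            if count:
                clean[str(element)] = int(count)
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: Optional[str]) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``C6H12O6``.

        ``None`` (or NA markers) gives an *unknown* formula; the empty string
        gives a *known, massless* formula (used for pseudo-species such as
        photons, which balance trivially).
        """
        if text is None or (isinstance(text, str) and text.upper() in {"NA", "NONE", "X"}):
            return cls(unknown=True)
        if text == "":
            return cls({})
        counts: Dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise ModelParseError(f"malformed formula {text!r} at {pos}")
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text):
            raise ModelParseError(f"malformed formula {text!r} at {pos}")
        return cls(counts)

    def to_string(self) -> str:
        if self.unknown:
            return ""
        parts = []
        for element in sorted(self.counts, key=lambda e: (e != "C", e != "H", e)):
            n = self.counts[element]
            parts.append(element + (str(n) if n != 1 else ""))
        return "".join(parts)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    @property
    def mass(self) -> float:
        """Molar mass in g/mol (NaN for unknown formulae)."""
        if self.unknown:
            return math.nan
        return sum(ATOMIC_MASSES[el] * n for el, n in self.counts.items())


# ---------------------------------------------------------------------------
# Metabolites and reactions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: ElementalFormula = field(default_factory=lambda: ElementalFormula(unknown=True))
    boundary: bool = False  # SBML boundaryCondition: excluded from S rows


def normalize_ec(ec: str) -> Tuple[str, bool]:
    """Normalize an EC string to four fields.

    Returns ``(normalized, partial)`` where ``partial`` is True when any field
    is missing or a dash.  ``"1.1.1"`` → ``("1.1.1.-", True)``.
    """
    fields = [f.strip() or "-" for f in ec.strip().removeprefix("EC").strip().split(".")]
    fields = (fields + ["-"] * 4)[:4]
    return ".".join(fields), "-" in fields


@dataclass
class Reaction:
    """A stoichiometric reaction; negative coefficients are consumed species."""

    id: str
    name: str = ""
    stoichiometry: Dict[str, Fraction] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gene_association: str = ""
    ec_numbers: Tuple[str, ...] = ()
    subsystem: str = ""
    kind: str = "metabolic"

    def __post_init__(self) -> None:
        self.stoichiometry = {
            m: Fraction(c) for m, c in self.stoichiometry.items() if Fraction(c) != 0
        }
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(f"{self.id}: unknown reaction kind {self.kind!r}")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"{self.id}: lower bound {self.lower_bound} exceeds upper {self.upper_bound}"
            )
        self.ec_numbers = tuple(normalize_ec(e)[0] for e in self.ec_numbers)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def genes(self) -> frozenset:
        tokens = re.findall(r"[^\s()]+", self.gene_association)
        return frozenset(t for t in tokens if t.lower() not in {"and", "or"})

    def equation(self) -> str:
        """Human/TSV-readable equation, e.g. ``2 a_c + b_c -> c_h``."""
        def side(items):
            return " + ".join(
                (f"{abs(c)} {m}" if abs(c) != 1 else m)
                for m, c in sorted(items)
            )
        lhs = [(m, c) for m, c in self.stoichiometry.items() if c < 0]
        rhs = [(m, c) for m, c in self.stoichiometry.items() if c > 0]
        arrow = "<->" if self.reversible else "->"
        return f"{side(lhs)} {arrow} {side(rhs)}".strip()

    def copy(self) -> "Reaction":
        new = replace(self)
        new.stoichiometry = dict(self.stoichiometry)
        return new


_EQN_ARROWS = ("<->", "<=>", "-->", "->", "=>")


def parse_equation(text: str) -> Tuple[Dict[str, Fraction], bool]:
    """Parse ``2 a_c + b_c -> c_h`` into a stoichiometry map and reversibility."""
    arrow = next((a for a in _EQN_ARROWS if a in text), None)
    if arrow is None:
        raise ModelParseError(f"equation {text!r} has no arrow")
    lhs, rhs = text.split(arrow, 1)
    stoich: Dict[str, Fraction] = {}

    def eat(side: str, sign: int) -> None:
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 2:
                coeff, met = Fraction(parts[0]), parts[1]
            elif len(parts) == 1:
                coeff, met = Fraction(1), parts[0]
            else:
                raise ModelParseError(f"malformed term {term!r} in equation {text!r}")
            stoich[met] = stoich.get(met, Fraction(0)) + sign * coeff

    eat(lhs, -1)
    eat(rhs, +1)
    return stoich, arrow in ("<->", "<=>")


# ---------------------------------------------------------------------------
# The model container
# ---------------------------------------------------------------------------

@dataclass
class MetabolicModel:
    id: str = "model"
    compartments: Dict[str, str] = field(default_factory=dict)  # code -> name
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    biomass_reaction_id: Optional[str] = None
    atpm_reaction_id: Optional[str] = None
    notes: str = ""

    # -- construction ------------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        if met.compartment not in self.compartments:
            raise ModelValidationError(
                f"metabolite {met.id!r}: undeclared compartment {met.compartment!r}"
            )
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
        self.reactions[rxn.id] = rxn

    def remove_reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions.pop(rxn_id)
        except KeyError:
            raise ModelValidationError(f"no reaction {rxn_id!r}") from None

    @property
    def genes(self) -> frozenset:
        out: set = set()
        for rxn in self.reactions.values():
            out |= rxn.genes
        return frozenset(out)

    def validate(self) -> None:
        """Check all structural invariants; raise ModelValidationError on failure."""
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {met.id!r}: undeclared compartment {met.compartment!r}"
                )
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )
            if not rxn.stoichiometry and rxn.kind != "exchange":
                raise ModelValidationError(f"reaction {rxn.id!r} has empty stoichiometry")
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(f"reaction {rxn.id!r} has inverted bounds")
        for attr in ("biomass_reaction_id", "atpm_reaction_id"):
            rid = getattr(self, attr)
            if rid is not None and rid not in self.reactions:
                raise ModelValidationError(f"{attr} {rid!r} does not resolve")

    def copy(self) -> "MetabolicModel":
        new = MetabolicModel(
            id=self.id,
            compartments=dict(self.compartments),
            metabolites=dict(self.metabolites),
            reactions={rid: r.copy() for rid, r in self.reactions.items()},
            biomass_reaction_id=self.biomass_reaction_id,
            atpm_reaction_id=self.atpm_reaction_id,
            notes=self.notes,
        )
        return new

    def exchanges(self) -> List[str]:
        return [rid for rid, r in self.reactions.items() if r.kind == "exchange"]

    def model_hash(self) -> str:
        """Stable digest over all fields; used to assert no-mutation contracts."""
        import hashlib

        return hashlib.sha256(_to_json_str(self).encode()).hexdigest()


# ---------------------------------------------------------------------------
# Stoichiometric matrix
# ---------------------------------------------------------------------------

@dataclass
class StoichMatrix:
    """Sparse S with one row per non-boundary metabolite, one column per reaction."""

    matrix: sparse.csr_matrix
    metabolite_index: Dict[str, int]
    reaction_index: Dict[str, int]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.matrix.shape

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()


def stoichiometric_matrix(model: MetabolicModel) -> StoichMatrix:
    """Assemble S from a validated model; boundary metabolites are excluded."""
    model.validate()
    met_ids = [m.id for m in model.metabolites.values() if not m.boundary]
    met_index = {mid: i for i, mid in enumerate(met_ids)}
    rxn_index = {rid: j for j, rid in enumerate(model.reactions)}
    rows, cols, vals = [], [], []
    for rid, rxn in model.reactions.items():
        j = rxn_index[rid]
        for mid, coeff in rxn.stoichiometry.items():
            if mid in met_index:
                rows.append(met_index[mid])
                cols.append(j)
                vals.append(float(coeff))
    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(met_index), len(rxn_index))
    )
    return StoichMatrix(S, met_index, rxn_index)


def compartment_census(model: MetabolicModel) -> pd.DataFrame:
    """Reaction/metabolite counts per compartment plus a transport/exchange column.

    A metabolic/biomass/maintenance reaction is assigned to the compartment of
    its participants (majority vote on metabolite compartments, excluding the
    external compartment); transport and exchange reactions are tallied once in
    their own column, mirroring the usual model-census table.
    """
    model.validate()
    codes = [c for c in model.compartments if c != "e"]
    columns = codes + ["transport_exchange"]
    rxn_counts = {c: 0 for c in columns}
    met_counts = {c: 0 for c in codes}
    met_counts["transport_exchange"] = 0
    for met in model.metabolites.values():
        if met.compartment in met_counts:
            met_counts[met.compartment] += 1
    for rxn in model.reactions.values():
        if rxn.kind in ("transport", "exchange"):
            rxn_counts["transport_exchange"] += 1
            continue
        votes: Dict[str, int] = {}
        for mid in rxn.stoichiometry:
            comp = model.metabolites[mid].compartment
            if comp in codes:
                votes[comp] = votes.get(comp, 0) + 1
        if votes:
            best = max(sorted(votes), key=lambda c: votes[c])
            rxn_counts[best] += 1
        else:
            rxn_counts["transport_exchange"] += 1
    return pd.DataFrame(
        {"reactions": rxn_counts, "metabolites": met_counts},
        index=pd.Index(columns, name="compartment"),
    ).fillna(0).astype(int)


# ---------------------------------------------------------------------------
# JSON dialect (canonical)
# ---------------------------------------------------------------------------

def _to_json_obj(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "compartments": dict(sorted(model.compartments.items())),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": None if m.formula.unknown else m.formula.to_string(),
                "boundary": m.boundary,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {m: str(c) for m, c in sorted(r.stoichiometry.items())},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_association": r.gene_association,
                "ec_numbers": list(r.ec_numbers),
                "subsystem": r.subsystem,
                "kind": r.kind,
            }
            for r in model.reactions.values()
        ],
        "biomass_reaction_id": model.biomass_reaction_id,
        "atpm_reaction_id": model.atpm_reaction_id,
        "notes": model.notes,
    }


def _to_json_str(model: MetabolicModel) -> str:
    return json.dumps(_to_json_obj(model), indent=1, sort_keys=False)


def _from_json_obj(obj: dict) -> MetabolicModel:
    model = MetabolicModel(
        id=obj.get("id", "model"),
        compartments=dict(obj.get("compartments", {})),
        biomass_reaction_id=obj.get("biomass_reaction_id"),
        atpm_reaction_id=obj.get("atpm_reaction_id"),
        notes=obj.get("notes", ""),
    )
    for m in obj.get("metabolites", []):
        model.add_metabolite(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m["compartment"],
                formula=ElementalFormula.parse(m.get("formula")),
                boundary=bool(m.get("boundary", False)),
            )
        )
    for r in obj.get("reactions", []):
        model.add_reaction(
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={m: Fraction(c) for m, c in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                gene_association=r.get("gene_association", ""),
                ec_numbers=tuple(r.get("ec_numbers", ())),
                subsystem=r.get("subsystem", ""),
                kind=r.get("kind", "metabolic"),
            )
        )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML Level 3 + fbc dialect
# ---------------------------------------------------------------------------

def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sb = doc.createModel()
    sb.setId(model.id)
    mplug = sb.getPlugin("fbc")
    mplug.setStrict(False)
    if model.notes:
        sb.setNotes(f"<body xmlns='http://www.w3.org/1999/xhtml'><p>{model.notes}</p></body>")

    for code, name in model.compartments.items():
        comp = sb.createCompartment()
        comp.setId(code)
        comp.setName(name)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sb.createSpecies()
        sp.setId("M_" + met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(met.boundary)
        sp.setConstant(False)
        if not met.formula.unknown:
            text = met.formula.to_string()
            if text:
                sp.getPlugin("fbc").setChemicalFormula(text)
            else:  # massless pseudo-species (e.g. photon): carry via notes
                sp.setNotes(
                    "<body xmlns='http://www.w3.org/1999/xhtml'><p>MASSLESS: yes</p></body>"
                )

    bound_ids: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_ids:
            pid = f"B_{len(bound_ids)}"
            par = sb.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_ids[value] = pid
        return bound_ids[value]

    gene_ids: set = set()
    for rxn in model.reactions.values():
        for g in rxn.genes:
            if g not in gene_ids:
                gp = mplug.createGeneProduct()
                gp.setId("G_" + re.sub(r"\W", "_", g))
                gp.setLabel(g)
                gene_ids.add(g)

    for rxn in model.reactions.values():
        rx = sb.createReaction()
        rx.setId("R_" + rxn.id)
        rx.setName(rxn.name)
        rx.setReversible(rxn.reversible)
        rx.setFast(False)
        for mid, coeff in rxn.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies("M_" + mid)
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gene_association:
            gpa = rplug.createGeneProductAssociation()
            assoc = rxn.gene_association
            for g in sorted(rxn.genes, key=len, reverse=True):
                assoc = re.sub(rf"(?<![\w]){re.escape(g)}(?![\w])",
                               "G_" + re.sub(r"\W", "_", g), assoc)
            gpa.setAssociation(assoc)
        # kind/subsystem/EC go into notes key:value lines (round-trip carriers)
        lines = [f"KIND: {rxn.kind}"]
        if rxn.subsystem:
            lines.append(f"SUBSYSTEM: {rxn.subsystem}")
        if rxn.ec_numbers:
            lines.append("EC: " + ";".join(rxn.ec_numbers))
        body = "".join(f"<p>{ln}</p>" for ln in lines)
        rx.setNotes(f"<body xmlns='http://www.w3.org/1999/xhtml'>{body}</body>")

    objective_targets = [model.biomass_reaction_id, model.atpm_reaction_id]
    if model.biomass_reaction_id:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + model.biomass_reaction_id)
        fo.setCoefficient(1.0)
    # ATPM id carried in model notes so round trips stay lossless
    note_lines = []
    if model.atpm_reaction_id:
        note_lines.append(f"ATPM: {model.atpm_reaction_id}")
    if model.notes:
        note_lines.append(f"NOTES: {model.notes}")
    if note_lines:
        body = "".join(f"<p>{ln}</p>" for ln in note_lines)
        sb.setNotes(f"<body xmlns='http://www.w3.org/1999/xhtml'>{body}</body>")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def _notes_dict(node) -> Dict[str, str]:
    out: Dict[str, str] = {}
    if node.isSetNotes():
        text = node.getNotesString()
        for key, value in re.findall(r">\s*([A-Z]+):\s*([^<]*?)\s*<", text):
            out[key] = value
    return out


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise ModelParseError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sb = doc.getModel()
    if sb is None:
        raise ModelParseError(f"{path} contains no SBML model element")
    model = MetabolicModel(id=sb.getId() or "model")
    top_notes = _notes_dict(sb)
    model.atpm_reaction_id = top_notes.get("ATPM") or None
    model.notes = top_notes.get("NOTES", "")

    for i in range(sb.getNumCompartments()):
        comp = sb.getCompartment(i)
        model.compartments[comp.getId()] = comp.getName() or comp.getId()

    gene_labels: Dict[str, str] = {}
    mplug = sb.getPlugin("fbc")
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    for i in range(sb.getNumSpecies()):
        sp = sb.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = None
        if splug is not None and splug.isSetChemicalFormula():
            formula = splug.getChemicalFormula()
        elif _notes_dict(sp).get("MASSLESS"):
            formula = ""
        model.add_metabolite(
            Metabolite(
                id=sp.getId().removeprefix("M_"),
                name=sp.getName(),
                compartment=sp.getCompartment(),
                formula=ElementalFormula.parse(formula),
                boundary=sp.getBoundaryCondition(),
            )
        )

    params = {
        sb.getParameter(i).getId(): sb.getParameter(i).getValue()
        for i in range(sb.getNumParameters())
    }

    for i in range(sb.getNumReactions()):
        rx = sb.getReaction(i)
        stoich: Dict[str, Fraction] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            mid = ref.getSpecies().removeprefix("M_")
            stoich[mid] = stoich.get(mid, Fraction(0)) - _rationalize(ref.getStoichiometry())
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            mid = ref.getSpecies().removeprefix("M_")
            stoich[mid] = stoich.get(mid, Fraction(0)) + _rationalize(ref.getStoichiometry())
        rplug = rx.getPlugin("fbc")
        lb = params.get(rplug.getLowerFluxBound(), -DEFAULT_BOUND)
        ub = params.get(rplug.getUpperFluxBound(), DEFAULT_BOUND)
        gpr = ""
        if rplug.isSetGeneProductAssociation():
            gpr = rplug.getGeneProductAssociation().getAssociation().toInfix()
            for gid, label in gene_labels.items():
                gpr = re.sub(rf"(?<![\w]){re.escape(gid)}(?![\w])", label, gpr)
            gpr = _strip_outer_parens(gpr)
        notes = _notes_dict(rx)
        model.add_reaction(
            Reaction(
                id=rx.getId().removeprefix("R_"),
                name=rx.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_association=gpr,
                ec_numbers=tuple(e for e in notes.get("EC", "").split(";") if e),
                subsystem=notes.get("SUBSYSTEM", ""),
                kind=notes.get("KIND", "metabolic"),
            )
        )

    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getObjective(0)
        if obj.getNumFluxObjectives() > 0:
            model.biomass_reaction_id = (
                obj.getFluxObjective(0).getReaction().removeprefix("R_")
            )
    model.validate()
    return model


def _strip_outer_parens(text: str) -> str:
    """Drop parentheses that wrap the entire boolean expression."""
    text = text.strip()
    while text.startswith("(") and text.endswith(")"):
        depth = 0
        wraps = True
        for i, ch in enumerate(text):
            depth += ch == "("
            depth -= ch == ")"
            if depth == 0 and i < len(text) - 1:
                wraps = False
                break
        if not wraps:
            break
        text = text[1:-1].strip()
    return text


def _rationalize(value: float) -> Fraction:
    """Recover a small rational from an SBML double (10/3 survives round trips)."""
    return Fraction(value).limit_denominator(10**6)


# ---------------------------------------------------------------------------
# Tabular (TSV) dialect
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "reaction_id", "equation", "lower_bound", "upper_bound",
    "genes", "ec", "subsystem", "kind",
]


def _write_tabular(model: MetabolicModel, path: Path) -> None:
    rows = []
    for rxn in model.reactions.values():
        rows.append(
            {
                "reaction_id": rxn.id,
                "equation": rxn.equation(),
                "lower_bound": rxn.lower_bound,
                "upper_bound": rxn.upper_bound,
                "genes": rxn.gene_association,
                "ec": ";".join(rxn.ec_numbers),
                "subsystem": rxn.subsystem,
                "kind": rxn.kind,
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def _read_tabular(path: Path) -> MetabolicModel:
    try:
        table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ModelParseError(f"cannot read TSV {path}: {exc}") from exc
    missing = [c for c in ("reaction_id", "equation") if c not in table.columns]
    if missing:
        raise ModelParseError(f"TSV {path} lacks required column(s) {missing}")
    model = MetabolicModel(id=Path(path).stem)
    comps_seen: set = set()
    met_rows: List[Tuple[str, str]] = []
    parsed = []
    for i, row in table.iterrows():
        try:
            stoich, reversible = parse_equation(row["equation"])
        except ModelParseError as exc:
            raise ModelParseError(f"line {i + 2}: {exc}") from exc
        parsed.append((row, stoich, reversible))
        for mid in stoich:
            comp = mid.rsplit("_", 1)[-1] if "_" in mid else "c"
            comps_seen.add(comp)
            met_rows.append((mid, comp))
    for comp in sorted(comps_seen):
        model.compartments.setdefault(comp, comp)
    for mid, comp in sorted(set(met_rows)):
        model.add_metabolite(Metabolite(id=mid, compartment=comp))
    for row, stoich, reversible in parsed:
        lb = float(row.get("lower_bound") or (-DEFAULT_BOUND if reversible else 0.0))
        ub = float(row.get("upper_bound") or DEFAULT_BOUND)
        model.add_reaction(
            Reaction(
                id=row["reaction_id"],
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_association=row.get("genes", ""),
                ec_numbers=tuple(e for e in str(row.get("ec", "")).split(";") if e),
                subsystem=row.get("subsystem", ""),
                kind=row.get("kind") or "metabolic",
            )
        )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def read_model(path, format: Optional[str] = None) -> MetabolicModel:
    """Read a model from JSON, SBML, or tabular TSV (inferred from suffix)."""
    path = Path(path)
    fmt = format or {".json": "json", ".xml": "sbml", ".sbml": "sbml",
                     ".tsv": "tabular"}.get(path.suffix.lower())
    if fmt is None:
        raise ModelParseError(f"cannot infer format of {path}; pass format=")
    if fmt == "json":
        try:
            obj = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
        return _from_json_obj(obj)
    if fmt == "sbml":
        return _read_sbml(path)
    if fmt == "tabular":
        return _read_tabular(path)
    raise ModelParseError(f"unknown format {fmt!r}")


def write_model(model: MetabolicModel, path, format: Optional[str] = None) -> None:
    """Write a model to JSON (canonical), SBML L3+fbc, or tabular TSV."""
    model.validate()
    path = Path(path)
    fmt = format or {".json": "json", ".xml": "sbml", ".sbml": "sbml",
                     ".tsv": "tabular"}.get(path.suffix.lower())
    if fmt == "json":
        path.write_text(_to_json_str(model) + "\n")
    elif fmt == "sbml":
        _write_sbml(model, path)
    elif fmt == "tabular":
        _write_tabular(model, path)
    else:
        raise ModelParseError(f"unknown format {fmt!r}")
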