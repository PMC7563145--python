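"""Deterministic generator for "minidiatom", a compact photoautotroph model.

The generated network is a three-compartment (cytosol / chloroplast /
mitochondrion, plus an external compartment) diatom-like photoautotroph that
exhibits, at toy scale, every structural feature the analyses in this package
rely on:

* photon-driven linear electron flow (PSII → plastoquinone → cytochrome b6f →
  plastocyanin → PSI → ferredoxin → NADPH) with explicit thylakoid-lumen
  proton accounting and a 14/3 H+ : ATP plastidial ATP synthase;
* cyclic electron flow around PSI (ferredoxin → plastoquinone), producing
  lumen protons and hence ATP without NADPH;
* a Calvin–Benson–Bassham core (Rubisco, PGA reduction, a lumped RuBP
  regeneration step) with a triose-phosphate/Pi translocator and a PGA
  shuttle to the cytosol;
* the malate–oxaloacetate valve: NADPH-dependent plastidial malate
  dehydrogenase plus mal/OAA antiporters in both the chloroplast and the
  mitochondrial membranes, delivering reducing power to mitochondrial
  oxidative phosphorylation (P/O 2.5);
* silica uptake feeding a frustule pseudo-component of biomass, so silica
  availability limits growth;
* chrysolaminarin (β-1,3-glucan) synthesis and an export step acting as a
  carbon-overflow sink;
* nitrate assimilation split into cytosolic nitrate reductase (NADH) and
  plastidial nitrite reductase (NADPH), and a minimal urea cycle whose final
  arginase step only carries flux when nitrogen is supplied in excess;
* an ATP-maintenance drain in the cytosol.

Reduced carriers (plastocyanin, ferredoxin) are modelled as conserved
moieties that carry one hydrogen-equivalent when reduced, so every internal
reaction balances C, N, P, S and Si exactly (oxygen is also balanced
throughout; hydrogen is bookkept loosely because stromal protons are not
tracked).  No external NADH dehydrogenase or malate–aspartate shuttle is
included: the malate valve is deliberately the sole route for exporting
photosynthetic reducing power, which is what makes the valve-knockout
experiment activate cyclic electron flow.

The default configuration is fully deterministic; ``seed`` only perturbs the
biomass composition to produce QC-stable variants.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .core import (
    DEFAULT_BOUND,
    ElementalFormula,
    Metabolite,
    MetabolicModel,
    ModelValidationError,
    Reaction,
)

__all__ = [
    "MonomerSpec",
    "BiomassComposition",
    "ToyModelManifest",
    "build_biomass_reaction",
    "build_toy_photoautotroph",
]

WATER_MASS = 2 * 1.008 + 15.999

#: Measured-growth defaults used across the analyses (h⁻¹ and mmol/(gDCW·h)).
DEFAULT_GROWTH_RATE = 0.024
DEFAULT_ATPM = 1.5


# ---------------------------------------------------------------------------
# Biomass composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonomerSpec:
    """A representative monomer for one biomass class.

    ``bonds`` is the number of condensation waters released per residue when
    the monomer is polymerized into the macromolecule; the residue mass used
    for the stoichiometric coefficient is monomer mass − bonds·18.015.
    """

    metabolite_id: str
    formula: str
    weight: float = 1.0  # fraction within the class
    bonds: int = 0

    @property
    def monomer_mass(self) -> float:
        return ElementalFormula.parse(self.formula).mass

    @property
    def residue_mass(self) -> float:
        return self.monomer_mass - self.bonds * WATER_MASS


def _default_monomers() -> Dict[str, Tuple[MonomerSpec, ...]]:
    return {
        "protein": (
            MonomerSpec("glu_c", "C5H9NO4", 0.95, bonds=1),
            MonomerSpec("cys_h", "C3H7NO2S", 0.05, bonds=1),
        ),
        "carbohydrate": (MonomerSpec("glucan_c", "C6H10O5", bonds=0),),
        "lipid": (MonomerSpec("palm_h", "C16H32O2", bonds=0),),
        "rna": (MonomerSpec("amp_c", "C10H14N5O7P", bonds=1),),
        "dna": (MonomerSpec("damp_c", "C10H14N5O6P", bonds=1),),
        "pigment": (MonomerSpec("fuco_h", "C42H58O6", bonds=0),),
        "silica": (MonomerSpec("frustule_c", "O2Si", bonds=0),),
    }


@dataclass
class BiomassComposition:
    """Macromolecular composition of a gram of dry biomass.

    Fractions are g/gDCW and must be non-negative with a sum ≤ 1; any
    remainder is unspecified ash and is reported, not drawn from metabolism.
    GAM is the growth-associated maintenance in mmol ATP/gDCW folded into the
    biomass equation.
    """

    fractions: Dict[str, float] = field(
        default_factory=lambda: {
            "protein": 0.40,
            "carbohydrate": 0.25,
            "lipid": 0.20,
            "rna": 0.05,
            "dna": 0.01,
            "pigment": 0.01,
            "silica": 0.08,
        }
    )
    monomers: Dict[str, Tuple[MonomerSpec, ...]] = field(default_factory=_default_monomers)
    gam: float = 30.0

    def validate(self) -> None:
        for cls, frac in self.fractions.items():
            if frac < 0:
                raise ModelValidationError(f"negative mass fraction for {cls!r}: {frac}")
        total = sum(self.fractions.values())
        if total > 1 + 1e-9:
            raise ModelValidationError(f"mass fractions sum to {total:.4f} > 1")
        if total <= 0:
            raise ModelValidationError("all biomass fractions are zero (empty biomass)")
        for cls, frac in self.fractions.items():
            if frac > 0 and not self.monomers.get(cls):
                raise ModelValidationError(f"no monomer entry for biomass class {cls!r}")
        if self.gam < 0:
            raise ModelValidationError("GAM must be non-negative")

    @property
    def ash_fraction(self) -> float:
        return max(0.0, 1.0 - sum(self.fractions.values()))


def build_biomass_reaction(
    composition: BiomassComposition,
    reaction_id: str = "biomass",
    atp: str = "atp_c",
    adp: str = "adp_c",
    pi: str = "pi_c",
    water: str = "h2o_c",
) -> Reaction:
    """Assemble the biomass drain from a macromolecular composition.

    Coefficients are mmol precursor per gDCW (fraction·1000/residue mass);
    condensation water is released per peptide/phosphodiester bond so the
    consumed precursor mass equals the polymerized gram.  GAM appears as
    ``GAM ATP + GAM H2O → GAM ADP + GAM Pi``.
    """
    composition.validate()
    stoich: Dict[str, Fraction] = {}
    water_out = 0.0
    for cls, frac in composition.fractions.items():
        if frac <= 0:
            continue
        for spec in composition.monomers[cls]:
            if spec.weight <= 0:
                continue
            coeff = frac * spec.weight * 1000.0 / spec.residue_mass
            coeff_f = Fraction(coeff).limit_denominator(10**6)
            stoich[spec.metabolite_id] = stoich.get(spec.metabolite_id, Fraction(0)) - coeff_f
            water_out += float(coeff_f) * spec.bonds
    gam = Fraction(composition.gam).limit_denominator(10**6)
    stoich[atp] = stoich.get(atp, Fraction(0)) - gam
    stoich[adp] = stoich.get(adp, Fraction(0)) + gam
    stoich[pi] = stoich.get(pi, Fraction(0)) + gam
    net_water = (Fraction(water_out) - gam).limit_denominator(10**6)
    if net_water:
        stoich[water] = stoich.get(water, Fraction(0)) + net_water
    return Reaction(
        id=reaction_id,
        name="biomass formation",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=DEFAULT_BOUND,
        kind="biomass",
        subsystem="biomass",
    )


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass
class ToyModelManifest:
    """Role → reaction-id map plus analytic reference quantities."""

    roles: Dict[str, str]
    analytic: Dict[str, float]
    composition: BiomassComposition

    def reaction(self, role: str) -> str:
        try:
            return self.roles[role]
        except KeyError:
            raise KeyError(f"manifest has no role {role!r}") from None

    def validate_against(self, model: MetabolicModel) -> None:
        for role, rid in self.roles.items():
            if rid not in model.reactions:
                raise ModelValidationError(f"role {role!r} → missing reaction {rid!r}")


# ---------------------------------------------------------------------------
# Metabolite inventory
# ---------------------------------------------------------------------------

_METS: List[Tuple[str, str, str, str]] = [
    # id, name, compartment, formula ("" = massless, known)
    ("photon_e", "photon", "e", ""),
    ("co2_e", "carbon dioxide", "e", "CO2"),
    ("o2_e", "oxygen", "e", "O2"),
    ("no3_e", "nitrate", "e", "NO3"),
    ("so4_e", "sulfate", "e", "O4S"),
    ("sioh4_e", "silicic acid", "e", "H4O4Si"),
    ("pi_e", "phosphate", "e", "H3O4P"),
    ("h2o_e", "water", "e", "H2O"),
    ("glucan_e", "chrysolaminarin (glucan residue)", "e", "C6H10O5"),
    ("urea_e", "urea", "e", "CH4N2O"),
    # cytosol
    ("co2_c", "carbon dioxide", "c", "CO2"),
    ("o2_c", "oxygen", "c", "O2"),
    ("h2o_c", "water", "c", "H2O"),
    ("pi_c", "phosphate", "c", "H3O4P"),
    ("no3_c", "nitrate", "c", "NO3"),
    ("no2_c", "nitrite", "c", "NO2"),
    ("so4_c", "sulfate", "c", "O4S"),
    ("sioh4_c", "silicic acid", "c", "H4O4Si"),
    ("frustule_c", "frustule silica", "c", "O2Si"),
    ("glucan_c", "chrysolaminarin (glucan residue)", "c", "C6H10O5"),
    ("urea_c", "urea", "c", "CH4N2O"),
    ("gap_c", "glyceraldehyde 3-phosphate", "c", "C3H7O6P"),
    ("pga_c", "3-phosphoglycerate", "c", "C3H7O7P"),
    ("pyr_c", "pyruvate", "c", "C3H4O3"),
    ("oaa_c", "oxaloacetate", "c", "C4H4O5"),
    ("mal_c", "malate", "c", "C4H6O5"),
    ("akg_c", "2-oxoglutarate", "c", "C5H6O5"),
    ("glu_c", "glutamate", "c", "C5H9NO4"),
    ("nh4_c", "ammonium", "c", "H4N"),
    ("amp_c", "AMP", "c", "C10H14N5O7P"),
    ("damp_c", "dAMP", "c", "C10H14N5O6P"),
    ("atp_c", "ATP", "c", "C10H16N5O13P3"),
    ("adp_c", "ADP", "c", "C10H15N5O10P2"),
    ("nad_c", "NAD+", "c", "C21H27N7O14P2"),
    ("nadh_c", "NADH", "c", "C21H28N7O14P2"),
    ("orn_c", "ornithine", "c", "C5H12N2O2"),
    ("cp_c", "carbamoyl phosphate", "c", "CH4NO5P"),
    ("citr_c", "citrulline", "c", "C6H13N3O3"),
    ("arg_c", "arginine", "c", "C6H14N4O2"),
    # chloroplast
    ("photon_h", "photon", "h", ""),
    ("co2_h", "carbon dioxide", "h", "CO2"),
    ("o2_h", "oxygen", "h", "O2"),
    ("h2o_h", "water", "h", "H2O"),
    ("pi_h", "phosphate", "h", "H3O4P"),
    ("nh4_h", "ammonium", "h", "H4N"),
    ("no2_h", "nitrite", "h", "NO2"),
    ("so4_h", "sulfate", "h", "O4S"),
    ("atp_h", "ATP", "h", "C10H16N5O13P3"),
    ("adp_h", "ADP", "h", "C10H15N5O10P2"),
    ("nadp_h", "NADP+", "h", "C21H28N7O17P3"),
    ("nadph_h", "NADPH", "h", "C21H29N7O17P3"),
    ("hlum_h", "thylakoid lumen proton", "h", "H"),
    ("pq_h", "plastoquinone", "h", "C13H18O2"),
    ("pqh2_h", "plastoquinol", "h", "C13H20O2"),
    ("pc_ox_h", "plastocyanin (oxidized)", "h", "Cu"),
    ("pc_red_h", "plastocyanin (reduced)", "h", "HCu"),
    ("fd_ox_h", "ferredoxin (oxidized)", "h", "Fe2S2"),
    ("fd_red_h", "ferredoxin (reduced)", "h", "HFe2S2"),
    ("rubp_h", "ribulose 1,5-bisphosphate", "h", "C5H12O11P2"),
    ("pga_h", "3-phosphoglycerate", "h", "C3H7O7P"),
    ("gap_h", "glyceraldehyde 3-phosphate", "h", "C3H7O6P"),
    ("pyr_h", "pyruvate", "h", "C3H4O3"),
    ("acet_h", "acetyl unit", "h", "C2H4O2"),
    ("palm_h", "palmitate", "h", "C16H32O2"),
    ("fuco_h", "fucoxanthin", "h", "C42H58O6"),
    ("cys_h", "cysteine", "h", "C3H7NO2S"),
    ("oaa_h", "oxaloacetate", "h", "C4H4O5"),
    ("mal_h", "malate", "h", "C4H6O5"),
    # mitochondrion
    ("co2_m", "carbon dioxide", "m", "CO2"),
    ("o2_m", "oxygen", "m", "O2"),
    ("h2o_m", "water", "m", "H2O"),
    ("pi_m", "phosphate", "m", "H3O4P"),
    ("pyr_m", "pyruvate", "m", "C3H4O3"),
    ("acet_m", "acetyl unit", "m", "C2H4O2"),
    ("oaa_m", "oxaloacetate", "m", "C4H4O5"),
    ("mal_m", "malate", "m", "C4H6O5"),
    ("akg_m", "2-oxoglutarate", "m", "C5H6O5"),
    ("nad_m", "NAD+", "m", "C21H27N7O14P2"),
    ("nadh_m", "NADH", "m", "C21H28N7O14P2"),
    ("atp_m", "ATP", "m", "C10H16N5O13P3"),
    ("adp_m", "ADP", "m", "C10H15N5O10P2"),
]


def _rxn(
    rid: str,
    name: str,
    eqn: Dict[str, object],
    lb: float,
    ub: float,
    kind: str = "metabolic",
    subsystem: str = "",
    ec: Tuple[str, ...] = (),
    genes: str = "",
) -> Reaction:
    return Reaction(
        id=rid,
        name=name,
        stoichiometry={m: Fraction(c) for m, c in eqn.items()},
        lower_bound=lb,
        upper_bound=ub,
        kind=kind,
        subsystem=subsystem,
        ec_numbers=ec,
        gene_association=genes,
    )


def _reaction_inventory() -> List[Reaction]:
    B = DEFAULT_BOUND
    R: List[Reaction] = []

    # --- exchanges (uptake positive on supply-style columns) ---------------
    ex = [
        ("EX_photon", "photon supply", {"photon_e": 1}, 0, B),
        ("EX_co2", "CO2 supply", {"co2_e": 1}, -B, B),
        ("EX_o2", "O2 evolution", {"o2_e": -1}, -B, B),
        ("EX_no3", "nitrate supply", {"no3_e": 1}, 0, B),
        ("EX_so4", "sulfate supply", {"so4_e": 1}, 0, B),
        ("EX_sioh4", "silicic acid supply", {"sioh4_e": 1}, 0, B),
        ("EX_pi", "phosphate supply", {"pi_e": 1}, 0, B),
        ("EX_h2o", "water exchange", {"h2o_e": 1}, -B, B),
        ("EX_chryso", "chrysolaminarin accumulation", {"glucan_e": -1}, 0, B),
        ("EX_urea", "urea excretion", {"urea_e": -1}, 0, B),
    ]
    for rid, name, st, lb, ub in ex:
        R.append(_rxn(rid, name, st, lb, ub, kind="exchange", subsystem="exchange"))

    # --- transporters ------------------------------------------------------
    tx = [
        ("photon_tx", "photon capture", {"photon_e": -1, "photon_h": 1}, 0, B),
        ("co2_tx", "CO2 diffusion (plasma membrane)", {"co2_e": -1, "co2_c": 1}, -B, B),
        ("co2_htx", "CO2 diffusion (chloroplast)", {"co2_c": -1, "co2_h": 1}, -B, B),
        ("co2_mtx", "CO2 diffusion (mitochondrion)", {"co2_c": -1, "co2_m": 1}, -B, B),
        ("o2_tx", "O2 diffusion (plasma membrane)", {"o2_c": -1, "o2_e": 1}, -B, B),
        ("o2_htx", "O2 diffusion (chloroplast)", {"o2_h": -1, "o2_c": 1}, -B, B),
        ("o2_mtx", "O2 diffusion (mitochondrion)", {"o2_c": -1, "o2_m": 1}, -B, B),
        ("no3_tx", "nitrate uptake", {"no3_e": -1, "no3_c": 1}, 0, B),
        ("no2_htx", "nitrite import (chloroplast)", {"no2_c": -1, "no2_h": 1}, 0, B),
        ("so4_tx", "sulfate uptake", {"so4_e": -1, "so4_c": 1}, 0, B),
        ("so4_htx", "sulfate import (chloroplast)", {"so4_c": -1, "so4_h": 1}, 0, B),
        ("si_tx", "silicic acid uptake", {"sioh4_e": -1, "sioh4_c": 1}, 0, B),
        ("pi_tx", "phosphate uptake", {"pi_e": -1, "pi_c": 1}, 0, B),
        ("pi_htx", "phosphate carrier (chloroplast)", {"pi_c": -1, "pi_h": 1}, -B, B),
        ("pi_mtx", "phosphate carrier (mitochondrion)", {"pi_c": -1, "pi_m": 1}, -B, B),
        ("h2o_tx", "water flux (plasma membrane)", {"h2o_e": -1, "h2o_c": 1}, -B, B),
        ("h2o_htx", "water flux (chloroplast)", {"h2o_c": -1, "h2o_h": 1}, -B, B),
        ("h2o_mtx", "water flux (mitochondrion)", {"h2o_c": -1, "h2o_m": 1}, -B, B),
        ("chryso_tx", "chrysolaminarin export", {"glucan_c": -1, "glucan_e": 1}, 0, B),
        ("urea_tx", "urea export", {"urea_c": -1, "urea_e": 1}, 0, B),
        ("tpt_tx", "triose phosphate/Pi translocator",
         {"gap_h": -1, "pi_c": -1, "gap_c": 1, "pi_h": 1}, -B, B),
        ("pga_tx", "3-phosphoglycerate shuttle", {"pga_c": -1, "pga_h": 1}, -B, B),
        ("pyr_htx", "pyruvate carrier (chloroplast)", {"pyr_h": -1, "pyr_c": 1}, -B, B),
        ("pyr_mtx", "pyruvate carrier (mitochondrion)", {"pyr_c": -1, "pyr_m": 1}, -B, B),
        ("akg_mtx", "2-oxoglutarate carrier", {"akg_m": -1, "akg_c": 1}, -B, B),
        ("nh4_htx", "ammonium carrier (chloroplast)", {"nh4_h": -1, "nh4_c": 1}, -B, B),
        ("oaa_mal_chlo_tx", "malate-oxaloacetate shuttle (chloroplast)",
         {"mal_h": -1, "oaa_c": -1, "mal_c": 1, "oaa_h": 1}, -B, B),
        ("oaa_mal_mito_tx", "malate-oxaloacetate shuttle (mitochondrion)",
         {"mal_c": -1, "oaa_m": -1, "mal_m": 1, "oaa_c": 1}, -B, B),
        ("atp_adp_mito_tx", "ADP/ATP translocase (mitochondrion)",
         {"atp_m": -1, "adp_c": -1, "adp_m": 1, "atp_c": 1}, -B, B),
        ("atp_adp_chlo_tx", "ADP/ATP translocase (chloroplast)",
         {"atp_h": -1, "adp_c": -1, "adp_h": 1, "atp_c": 1}, -B, B),
    ]
    for rid, name, st, lb, ub in tx:
        R.append(_rxn(rid, name, st, lb, ub, kind="transport", subsystem="transport"))

    # --- chloroplast: light reactions -------------------------------------
    light = "photosynthesis light reactions"
    R += [
        _rxn("psii", "photosystem II",
             {"photon_h": -4, "h2o_h": -2, "pq_h": -2,
              "o2_h": 1, "pqh2_h": 2, "hlum_h": 4},
             0, B, subsystem=light, ec=("1.10.3.9",), genes="psbA and psbD"),
        _rxn("cytb6f", "cytochrome b6f complex",
             {"pqh2_h": -1, "pc_ox_h": -2, "pq_h": 1, "pc_red_h": 2, "hlum_h": 4},
             0, B, subsystem=light, ec=("7.1.1.6",), genes="petB"),
        _rxn("psi", "photosystem I",
             {"photon_h": -2, "pc_red_h": -2, "fd_ox_h": -2,
              "pc_ox_h": 2, "fd_red_h": 2},
             0, B, subsystem=light, ec=("1.97.1.12",), genes="psaA and psaB"),
        _rxn("fnr", "ferredoxin-NADP+ reductase",
             {"fd_red_h": -2, "nadp_h": -1, "fd_ox_h": 2, "nadph_h": 1},
             0, B, subsystem=light, ec=("1.18.1.2",), genes="petH"),
        _rxn("cef", "cyclic electron flow (ferredoxin-plastoquinone)",
             {"fd_red_h": -2, "pq_h": -1, "fd_ox_h": 2, "pqh2_h": 1},
             0, B, subsystem=light, genes="pgr5"),
        _rxn("atpase_h", "plastidial ATP synthase (14 H+/3 ATP)",
             {"hlum_h": -14, "adp_h": -3, "pi_h": -3, "atp_h": 3, "h2o_h": 3},
             0, B, subsystem=light, ec=("7.1.2.2",), genes="atpB"),
    ]

    # --- chloroplast: carbon and biosynthesis ------------------------------
    cbb = "Calvin-Benson-Bassham cycle"
    R += [
        _rxn("rubisco", "ribulose-bisphosphate carboxylase",
             {"rubp_h": -1, "co2_h": -1, "h2o_h": -1, "pga_h": 2},
             0, B, subsystem=cbb, ec=("4.1.1.39",), genes="rbcL and rbcS"),
        _rxn("pga_red_h", "phosphoglycerate reduction (PGK + GAPDH)",
             {"pga_h": -1, "atp_h": -1, "nadph_h": -1,
              "gap_h": 1, "adp_h": 1, "pi_h": 1, "nadp_h": 1},
             0, B, subsystem=cbb, ec=("1.2.1.13",), genes="gapA"),
        _rxn("cbb_regen", "RuBP regeneration (lumped)",
             {"gap_h": -5, "atp_h": -3, "h2o_h": -2,
              "rubp_h": 3, "adp_h": 3, "pi_h": 2},
             0, B, subsystem=cbb, genes="prk"),
        _rxn("gly2_h", "plastid pyruvate kinase (lower glycolysis, lumped)",
             {"pga_h": -1, "adp_h": -1, "pyr_h": 1, "atp_h": 1, "h2o_h": 1},
             0, B, subsystem="glycolysis", ec=("2.7.1.40",), genes="pyk1"),
        _rxn("pdh_h", "plastid pyruvate dehydrogenase (NADP)",
             {"pyr_h": -1, "nadp_h": -1, "h2o_h": -1,
              "acet_h": 1, "co2_h": 1, "nadph_h": 1},
             0, B, subsystem="pyruvate metabolism", ec=("1.2.4.1",), genes="ptaC"),
        _rxn("fas_h", "fatty acid synthesis (C16, lumped)",
             {"acet_h": -8, "nadph_h": -14, "atp_h": -7,
              "palm_h": 1, "nadp_h": 14, "adp_h": 7, "pi_h": 7, "h2o_h": 7},
             0, B, subsystem="fatty acid biosynthesis", ec=("2.3.1.85",), genes="fas1"),
        _rxn("pig_syn_h", "fucoxanthin synthesis (lumped)",
             {"acet_h": -21, "nadph_h": -15, "atp_h": -6,
              "fuco_h": 1, "nadp_h": 15, "adp_h": 6, "pi_h": 6, "h2o_h": 30},
             0, B, subsystem="carotenoid and pigment biosynthesis", genes="pds or zds"),
        _rxn("nir_h", "nitrite reductase (ferredoxin-type, lumped to NADPH)",
             {"no2_h": -1, "nadph_h": -3, "nh4_h": 1, "nadp_h": 3, "h2o_h": 2},
             0, B, subsystem="nitrogen assimilation", ec=("1.7.7.1",), genes="nirA"),
        _rxn("cys_syn_h", "cysteine synthesis (sulfate assimilation, lumped)",
             {"gap_h": -1, "so4_h": -1, "nh4_h": -1, "nadph_h": -5, "atp_h": -1,
              "cys_h": 1, "nadp_h": 5, "adp_h": 1, "pi_h": 2, "h2o_h": 3},
             0, B, subsystem="sulfur and cysteine metabolism", ec=("2.5.1.47",),
             genes="cysK"),
        _rxn("mdh_h", "plastidial malate dehydrogenase (NADPH)",
             {"oaa_h": -1, "nadph_h": -1, "mal_h": 1, "nadp_h": 1},
             0, B, subsystem="malate valve", ec=("1.1.1.82",), genes="mdh2"),
    ]

    # --- cytosol ------------------------------------------------------------
    R += [
        _rxn("gly1_c", "GAPDH + PGK (upper payoff, reversible)",
             {"gap_c": -1, "nad_c": -1, "adp_c": -1, "pi_c": -1,
              "pga_c": 1, "nadh_c": 1, "atp_c": 1},
             -B, B, subsystem="glycolysis", ec=("1.2.1.12",), genes="gapC"),
        _rxn("gly2_c", "pyruvate kinase (lower glycolysis, lumped)",
             {"pga_c": -1, "adp_c": -1, "pyr_c": 1, "atp_c": 1, "h2o_c": 1},
             0, B, subsystem="glycolysis", ec=("2.7.1.40",), genes="pyk2"),
        _rxn("nr_c", "nitrate reductase (NADH)",
             {"no3_c": -1, "nadh_c": -1, "no2_c": 1, "nad_c": 1, "h2o_c": 1},
             0, B, subsystem="nitrogen assimilation", ec=("1.7.1.1",), genes="nr1"),
        _rxn("gdh_c", "glutamate dehydrogenase (NADH)",
             {"akg_c": -1, "nh4_c": -1, "nadh_c": -1,
              "glu_c": 1, "nad_c": 1, "h2o_c": 1},
             0, B, subsystem="amino acid metabolism", ec=("1.4.1.2",), genes="gdhA"),
        _rxn("mdh_c", "cytosolic malate dehydrogenase (reductive)",
             {"oaa_c": -1, "nadh_c": -1, "mal_c": 1, "nad_c": 1},
             0, B, subsystem="malate valve", ec=("1.1.1.37",), genes="mdh1"),
        _rxn("glucan_syn_c", "chrysolaminarin synthesis (lumped)",
             {"gap_c": -2, "atp_c": -1, "h2o_c": -2,
              "glucan_c": 1, "adp_c": 1, "pi_c": 3},
             0, B, subsystem="carbohydrate storage", ec=("2.4.1.34",), genes="bgs1"),
        _rxn("nuc_syn_c", "AMP synthesis (lumped)",
             {"gap_c": Fraction(-10, 3), "nh4_c": -5, "atp_c": -6,
              "h2o_c": Fraction(-7, 3),
              "amp_c": 1, "adp_c": 6, "pi_c": Fraction(25, 3)},
             0, B, subsystem="nucleotide biosynthesis", genes="purA"),
        _rxn("dna_syn_c", "ribonucleotide reduction (lumped)",
             {"amp_c": -1, "nadh_c": -1, "damp_c": 1, "nad_c": 1, "h2o_c": 1},
             0, B, subsystem="nucleotide biosynthesis", ec=("1.17.4.1",), genes="nrdA"),
        _rxn("cps_c", "carbamoyl-phosphate synthase",
             {"nh4_c": -1, "co2_c": -1, "atp_c": -2, "h2o_c": -1,
              "cp_c": 1, "adp_c": 2, "pi_c": 1},
             0, B, subsystem="urea cycle", ec=("6.3.4.16",), genes="cpsIII"),
        _rxn("otc_c", "ornithine transcarbamylase",
             {"orn_c": -1, "cp_c": -1, "citr_c": 1, "pi_c": 1},
             0, B, subsystem="urea cycle", ec=("2.1.3.3",), genes="otc1"),
        _rxn("asl_c", "arginine synthesis (ASS + ASL, ammonium-lumped)",
             {"citr_c": -1, "nh4_c": -1, "atp_c": -1,
              "arg_c": 1, "adp_c": 1, "pi_c": 1},
             0, B, subsystem="urea cycle", ec=("6.3.4.5",), genes="assA"),
        _rxn("arginase_c", "arginase",
             {"arg_c": -1, "h2o_c": -1, "orn_c": 1, "urea_c": 1},
             0, B, subsystem="urea cycle", ec=("3.5.3.1",), genes="argH"),
        _rxn("frustule_syn_c", "frustule silica deposition",
             {"sioh4_c": -1, "frustule_c": 1, "h2o_c": 2},
             0, B, subsystem="silica frustule biogenesis", genes="sit1"),
        _rxn("atpm_c", "ATP maintenance (NGAM)",
             {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
             0, B, kind="maintenance", subsystem="maintenance"),
    ]

    # --- mitochondrion ------------------------------------------------------
    R += [
        _rxn("pdh_m", "pyruvate dehydrogenase",
             {"pyr_m": -1, "nad_m": -1, "h2o_m": -1,
              "acet_m": 1, "co2_m": 1, "nadh_m": 1},
             0, B, subsystem="pyruvate metabolism", ec=("1.2.4.1",), genes="pdhA"),
        _rxn("pc_m", "pyruvate carboxylase",
             {"pyr_m": -1, "co2_m": -1, "atp_m": -1, "h2o_m": -1,
              "oaa_m": 1, "adp_m": 1, "pi_m": 1},
             0, B, subsystem="anaplerosis", ec=("6.4.1.1",), genes="pyc1"),
        _rxn("tca_m", "citrate synthase → 2-oxoglutarate (lumped TCA arm)",
             {"acet_m": -1, "oaa_m": -1, "nad_m": -1,
              "akg_m": 1, "co2_m": 1, "nadh_m": 1},
             0, B, subsystem="TCA cycle", ec=("2.3.3.1",), genes="cs1 and idh1"),
        _rxn("mdh_m", "mitochondrial malate dehydrogenase (oxidative)",
             {"mal_m": -1, "nad_m": -1, "oaa_m": 1, "nadh_m": 1},
             0, B, subsystem="malate valve", ec=("1.1.1.37",), genes="mdh3"),
        _rxn("oxphos_m", "oxidative phosphorylation (P/O 2.5, lumped)",
             {"nadh_m": -1, "o2_m": Fraction(-1, 2),
              "adp_m": Fraction(-5, 2), "pi_m": Fraction(-5, 2),
              "nad_m": 1, "atp_m": Fraction(5, 2), "h2o_m": Fraction(7, 2)},
             0, B, subsystem="oxidative phosphorylation", ec=("7.1.1.2",),
             genes="cox1 or cox2"),
    ]
    return R


_ROLES: Dict[str, str] = {
    "PSII": "psii",
    "PSI": "psi",
    "CEF": "cef",
    "cytb6f": "cytb6f",
    "FNR": "fnr",
    "plastidial_ATP_synthase": "atpase_h",
    "mitochondrial_ATP_synthase": "oxphos_m",
    "Rubisco": "rubisco",
    "CBB_lump": "cbb_regen",
    "chrysolaminarin_synthesis": "glucan_syn_c",
    "chrysolaminarin_export": "chryso_tx",
    "OAA_MAL_chlo_tx": "oaa_mal_chlo_tx",
    "OAA_MAL_mito_tx": "oaa_mal_mito_tx",
    "TCA_lump": "tca_m",
    "Si_tx": "si_tx",
    "NO3_tx": "no3_tx",
    "CO2_tx": "co2_tx",
    "photon_tx": "photon_tx",
    "O2_tx": "o2_tx",
    "ATPM": "atpm_c",
    "biomass": "biomass",
    "urea_cycle_cps": "cps_c",
    "urea_cycle_otc": "otc_c",
    "urea_cycle_asl": "asl_c",
    "urea_cycle_arginase": "arginase_c",
}


# ---------------------------------------------------------------------------
# Analytic route-budget reference
# ---------------------------------------------------------------------------

def _route_budget(composition: BiomassComposition, atpm: float = 0.0) -> Dict[str, float]:
    """Photon/carbon budget per unit growth from aggregated route balances.

    This is an independent, hand-derived reduction of the network: linear
    electron flow produces 1 NADPH and 6 lumen protons (hence 9/7 ATP) per 4
    photons; the malate valve exports surplus NADPH to mitochondrial
    oxidative phosphorylation at P/O 2.5; pyruvate is made in the plastid;
    cytosolic NADH demand is met by the triose/PGA shuttle.  Solving the
    seven route balances (RuBP, PGA, GAP, plastid NADPH, plastid ATP,
    cytosol+mito ATP, cytosol NADH) for one unit of growth yields the photon
    and net-CO2 requirements against which full LP solutions are checked.
    """
    composition.validate()
    coeff: Dict[str, float] = {}
    for cls, frac in composition.fractions.items():
        for spec in composition.monomers.get(cls, ()):
            if frac > 0 and spec.weight > 0:
                coeff[spec.metabolite_id] = coeff.get(spec.metabolite_id, 0.0) + (
                    frac * spec.weight * 1000.0 / spec.residue_mass
                )
    a_glu = coeff.get("glu_c", 0.0)
    a_cys = coeff.get("cys_h", 0.0)
    a_glucan = coeff.get("glucan_c", 0.0)
    a_palm = coeff.get("palm_h", 0.0)
    a_amp = coeff.get("amp_c", 0.0)
    a_damp = coeff.get("damp_c", 0.0)
    a_fuco = coeff.get("fuco_h", 0.0)
    gam = composition.gam

    pyr = 2 * a_glu + 8 * a_palm + 21 * a_fuco           # plastid pyruvate kinase
    gap_c_direct = 2 * a_glucan + Fraction(10, 3) * (a_amp + a_damp)
    n_no3 = a_glu + a_cys + 5 * (a_amp + a_damp)
    nadh_c_demand = n_no3 + a_glu + a_damp               # NR + GDH + RNR
    h = float(nadh_c_demand)                              # gly1 flux (NADH source)
    gap_c_total = float(gap_c_direct) + h

    # unknowns: r (rubisco), e (regen), d (PGA reduction), L (LEF), V (valve),
    #           Eh (plastid ATP export), Em (mito ATP export)
    # balances:
    #   RuBP:        3e - r = 0
    #   PGA (h):     2r + h - d - pyr = 0          (pga_tx returns h)
    #   GAP (h):     d - 5e - gap_c_total - a_cys = 0
    #   NADPH (h):   L + pdh_h - d - 3 n_no3 - 5 a_cys - 14 a_palm - 15 a_fuco - V = 0
    #   ATP (h):     (9/7) L + pyr - d - 3e - a_cys - 7 a_palm - 6 a_fuco - Eh = 0
    #   ATP (c+m):   h + Eh + Em - gam - atpm - a_glucan - 6 (a_amp + a_damp) = 0
    #   ATP (m):     2.5 (2 a_glu + V) - a_glu - Em = 0
    pdh_h = 8 * a_palm + 21 * a_fuco
    A = np.zeros((7, 7))
    b = np.zeros(7)
    # order: r, e, d, L, V, Eh, Em
    A[0] = [-1, 3, 0, 0, 0, 0, 0]
    A[1] = [2, 0, -1, 0, 0, 0, 0]; b[1] = pyr - h
    A[2] = [0, -5, 1, 0, 0, 0, 0]; b[2] = gap_c_total + a_cys
    A[3] = [0, 0, -1, 1, -1, 0, 0]
    b[3] = 3 * n_no3 + 5 * a_cys + 14 * a_palm + 15 * a_fuco - pdh_h
    A[4] = [0, 0, -1, 9 / 7, 0, -1, 0]
    b[4] = a_cys + 7 * a_palm + 6 * a_fuco - pyr
    A[4][1] = -3
    A[5] = [0, 0, 0, 0, 0, 1, 1]
    b[5] = gam + atpm + a_glucan + 6 * (a_amp + a_damp) - h
    A[6] = [0, 0, 0, 0, 2.5, 0, -1]; b[6] = a_glu - 5 * a_glu
    x = np.linalg.solve(A, b)
    r, e, d, L, V, Eh, Em = x
    carbon = (
        5 * a_glu + 3 * a_cys + 6 * a_glucan + 16 * a_palm
        + 10 * (a_amp + a_damp) + 42 * a_fuco
    )
    return {
        "photons_per_gdcw": 4 * L,
        "net_co2_per_gdcw": carbon,
        "valve_nadph_per_gdcw": V,
        "photons_per_net_co2": 4 * L / carbon,
        "rubisco_per_gdcw": r,
    }


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

PHOTON_BUDGET = 10.0  # mmol/(gDCW·h) used for the analytic max-growth reference


def build_toy_photoautotroph(
    composition: Optional[BiomassComposition] = None,
    seed: Optional[int] = None,
) -> Tuple[MetabolicModel, ToyModelManifest]:
    """Build the deterministic toy photoautotroph and its manifest.

    ``seed`` perturbs the biomass mass fractions by up to ±10 % (renormalized
    to the default total) to produce structurally identical variants; the
    default configuration is fully deterministic.
    """
    composition = composition or BiomassComposition()
    if seed is not None:
        rng = np.random.default_rng(seed)
        fr = dict(composition.fractions)
        total = sum(fr.values())
        jitter = {k: v * float(rng.uniform(0.9, 1.1)) for k, v in fr.items()}
        scale = total / sum(jitter.values())
        composition = BiomassComposition(
            fractions={k: v * scale for k, v in jitter.items()},
            monomers=dict(composition.monomers),
            gam=composition.gam,
        )
    composition.validate()

    model = MetabolicModel(
        id="minidiatom",
        compartments={
            "c": "cytosol",
            "h": "chloroplast",
            "m": "mitochondrion",
            "e": "external",
        },
        notes="synthetic three-compartment photoautotroph (toy scale)",
    )
    for mid, name, comp, formula in _METS:
        model.add_metabolite(
            Metabolite(mid, name=name, compartment=comp,
                       formula=ElementalFormula.parse(formula))
        )
    for rxn in _reaction_inventory():
        model.add_reaction(rxn)
    model.add_reaction(build_biomass_reaction(composition))
    model.biomass_reaction_id = "biomass"
    model.atpm_reaction_id = "atpm_c"
    model.validate()

    budget = _route_budget(composition, atpm=0.0)
    analytic = {
        "photon_budget": PHOTON_BUDGET,
        "max_growth_at_photon_budget": PHOTON_BUDGET / budget["photons_per_gdcw"],
        "photons_per_gdcw": budget["photons_per_gdcw"],
        "net_co2_per_gdcw": budget["net_co2_per_gdcw"],
        "photons_per_net_co2": budget["photons_per_net_co2"],
        "valve_nadph_per_gdcw": budget["valve_nadph_per_gdcw"],
    }
    manifest = ToyModelManifest(roles=dict(_ROLES), analytic=analytic,
                                composition=composition)
    manifest.validate_against(model)
    return model, manifest
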