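# Methods

## The modelling framework

All analyses operate on a compartmentalized stoichiometric model: metabolites
with integer elemental formulae, reactions with rational coefficients and
flux bounds in mmol/(gDCW·h), organised into cytosol (`c`), chloroplast
(`h`), mitochondrion (`m`) and an external compartment (`e`). Exchange
reactions are single-participant supply/drain columns written in the
"external → internal" orientation, so nutrient uptake is a positive flux and
export reactions (O₂ evolution, chrysolaminarin accumulation, urea excretion)
are positive in the export direction. Reactions without curated bounds
default to ±1000 (reversible) or [0, 1000] (irreversible).

The core simulation is total-flux minimization at fixed growth rate t and
fixed ATP maintenance m: minimize Σ|vᵢ| subject to S·v = 0, v_biomass = t,
v_ATPM = m. The absolute values are handled by the standard forward/reverse
split (v = p − q, p, q ≥ 0), giving an ordinary LP solved with HiGHS through
scipy. Growth is an equality, not a lower bound, so the optimizer cannot
trade growth against flux parsimony.

### Numerical choices

* LP feasibility/duality tolerances 1e-9; reported fluxes below 1e-6 are
  rounded to zero; steady-state residual of accepted solutions ≤ 1e-6.
* Producibility (gap) tolerance: a precursor is gapped when its maximal
  temporary-sink flux is ≤ 1e-9.
* HiGHS is deterministic, so the returned vertex is reproducible run to run.
  Optima may still be degenerate in flux space: any flux quoted as a point
  estimate should first be certified by `fixed_objective_variability`
  (range width ≤ 1e-6 at the frozen total-flux optimum). The cyclic-electron-
  flow zero in the reference state carries such a certificate; some interior
  energy-shuttling fluxes (e.g. the split of cytosolic NADH oxidation across
  alternative shuttles) are genuinely non-unique and are reported only as
  scan aggregates.
* Constraint semantics: equality fixes and knockouts *intersect* with
  existing bounds. Deleting a reaction whose flux is independently demanded
  (the biomass drain at fixed growth, the maintenance drain at fixed ATPM)
  therefore yields an infeasible — essential — verdict rather than silently
  erasing the demand.

## The synthetic photoautotroph ("minidiatom")

The generator emits a deterministic 76-reaction, 81-metabolite network
holding every structural feature the analyses exercise. Design choices worth
knowing:

* **Light reactions.** Linear electron flow is resolved into PSII (4 photons,
  2 H₂O → O₂ + 2 plastoquinol + 4 lumen H⁺), cytochrome b6f (Q-cycle, 4 lumen
  H⁺ per plastoquinol), plastocyanin, PSI and ferredoxin-NADP⁺ reductase; per
  NADPH the chain absorbs 4 photons and deposits 6 lumen protons. The
  plastidial ATP synthase uses the textbook 14/3 H⁺:ATP ratio, so LEF
  supplies 9/7 ≈ 1.29 ATP per NADPH. Cyclic electron flow
  (ferredoxin → plastoquinone) yields ATP without NADPH. Reduced carriers
  are conserved moieties carrying one hydrogen-equivalent, which keeps all
  internal reactions exactly balanced for C, N, P, S, Si and O (hydrogen is
  bookkept loosely; stromal protons are not tracked and charge balance is
  not enforced — the balance checker reports H imbalances informationally).
* **Carbon core.** Rubisco, a PGA-reduction step, and a lumped RuBP
  regeneration (5 GAP + 3 ATP → 3 RuBP) keep the Calvin cycle hand-
  verifiable. A triose-phosphate/Pi antiporter and a PGA shuttle connect
  plastid and cytosol; lower glycolysis exists in both compartments.
* **Energetics.** The malate–oxaloacetate valve (NADPH-dependent plastidial
  malate dehydrogenase plus mal/OAA antiporters in both membranes) is the
  *only* route for exporting photosynthetic reducing power, consistent with
  reports that diatoms lack a malate–aspartate shuttle; no external
  mitochondrial NADH dehydrogenase is included. Mitochondrial oxidative
  phosphorylation is lumped at P/O 2.5; ADP/ATP translocases connect both
  organelles to the cytosol. With these choices the headline behaviours are
  *emergent*: the wild-type optimum uses LEF + valve (CEF = 0) because that
  route costs fewer photons per ATP, and knocking out the mitochondrial
  antiporter leaves CEF as the only closure of the plastid ATP/NADPH budget.
* **Growth.** The biomass equation is assembled from a macromolecular
  composition (defaults, g/gDCW: protein 0.40, carbohydrate 0.25, lipid
  0.20, RNA 0.05, DNA 0.01, pigment 0.01, silica 0.08; these are plausible
  stand-ins — measured values belong in a user-supplied composition).
  Coefficients are fraction·1000/residue-mass with condensation water
  released per bond, so drawn precursor mass is exactly 1 g/gDCW.
  Growth-associated maintenance (GAM) defaults to 30 mmol ATP/gDCW, folded
  into the biomass equation; non-growth maintenance (NGAM/ATPM) defaults to
  1.5 mmol/(gDCW·h) as a separate fixed drain. The default growth rate is
  0.024 h⁻¹. Silica enters biomass as a frustule pseudo-component (SiO₂),
  making silicic-acid uptake stoichiometrically limiting for growth.
* **Nitrogen.** Nitrate reduction is split (cytosolic NADH-dependent nitrate
  reductase, plastidial nitrite reductase) and a minimal urea cycle
  (carbamoyl-phosphate synthase → ornithine transcarbamylase → a lumped
  arginine synthesis → arginase) exists whose arginase step carries flux only
  when nitrate supply is fixed above the biomass demand — excess nitrogen
  then leaves as urea.
* **Analytic reference.** The manifest stores a hand-derived route-balance
  optimum: solving the seven aggregate balances (RuBP, PGA, GAP, plastid
  NADPH, plastid ATP, cytosolic+mitochondrial ATP, cytosolic NADH) for one
  unit of growth gives the photon requirement per gDCW in closed form; the
  LP maximum growth at a fixed photon budget must equal budget/photons-per-
  gDCW. This is an independent derivation, not a re-run of the LP machinery,
  and it is asserted in the tests to machine precision.

### What the generator does and does not emulate

It reproduces the *topology and energetics* that drive the published
analyses: LEF/CEF competition, the malate valve, silica-limited growth with
carbohydrate overflow, partial TCA and urea-cycle activity, nitrogen and
sulfur assimilation costs. It does not attempt realistic pathway inventories
(single lumped reactions stand for fatty-acid, pigment, nucleotide and
amino-acid biosynthesis), gene–protein–reaction fidelity (gene labels are
illustrative), thermodynamics beyond irreversibility assignments, or kinetic
regulation. Passing tests therefore demonstrate the correctness of the
*methods* on a network with the right structure — not predictions for any
real organism; quantitative claims about a real diatom require its own
curated reconstruction as input.

## Analysis conventions

* **Silica scan.** Both the CO₂ and the silicic-acid uptake are fixed as
  equalities per scan row, growth is free, ATPM stays fixed, and total flux
  is minimized. Because the frustule is the only silica sink, biomass is
  pinned by the silica balance and the fixed carbon that biomass cannot
  absorb exits as chrysolaminarin — fixing only an upper bound on silica
  would instead let the flux-minimal solution route all carbon to the
  overflow polymer at zero growth, which defeats the purpose of the scan.
* **Maintenance scan.** ATPM swept over 0–8 mmol/(gDCW·h) (default step
  0.5) at fixed growth; plastidial and mitochondrial ATP synthesis are
  reported in ATP units (synthase flux × ATP stoichiometry) with both
  ratio orientations.
* **Valve knockout.** The default knockout target is the mitochondrial
  mal/OAA antiporter — the valve's obligatory membrane step; the chloroplast
  antiporter alone cannot carry the valve once the mitochondrial side is
  closed.
* **Essentiality.** Reactions whose flux range is [0, 0] with the growth and
  maintenance fixes relaxed are labelled *blocked* (their deletion is
  vacuous); the rest are deleted one at a time and classified by LP
  feasibility. Iteration follows model order, so reports are deterministic.
* **Yields.** Growth is fixed to growth_fraction × wild-type rate (default
  0.8 × 0.024 h⁻¹) and the CO₂ supply to 2.05 mmol/(gDCW·h) — the same value
  used for the silica scan; since the yield is the ratio v_product/v_CO₂ the
  choice only sets the scale. Product transport/exchange reactions (and, for
  heterologous products, the catalog module's pathway reactions) are added
  to a working copy and never persist; the carbon ceiling x·n_C ≤ 1 is
  asserted on every result. At growth fraction 0 with photons free the
  yield reaches the exact stoichiometric ceiling 1/n_C, because the energy
  budget (the malate valve) is carbon-neutral. The shipped heterologous
  catalog implements the usual engineering targets (isobutanol via kivD,
  PHB, citramalate, 2-methylsuccinate, styrene, 5-aminolevulinate, isoprene,
  valencene, farnesene, naringenin) as lumped carbon/N/P/S-balanced routes
  anchored on host metabolites so they are computable on the toy network;
  they are stoichiometric ceilings, not enzyme-level designs. Note the
  valencene entry carries more gene labels than reactions (synthase
  isoforms) — the catalog notes the ambiguity.
* **EC comparison.** Exact four-field EC matching; partial ECs (any `-`
  field) are excluded from the set algebra and counted separately. Category
  tallies use a subsystem-first, EC-prefix-fallback map; the shipped default
  map covers the broad pathway categories and will not reproduce any
  specific publication's hand-assigned tallies.

## Known limitations

* Proton and charge balance are not enforced; models curated to different
  proton conventions will show (reported, non-fatal) H imbalances.
* Gap filling is exhaustive over subsets of a user-supplied candidate pool
  (≤ 3 additions); it is meant for curation-scale pools, not for mining
  whole reaction databases — that would need a MILP formulation.
* pFBA degeneracy means individual interior fluxes can differ between runs
  of *different but equivalent* problems (e.g. after deleting a zero-flux
  reaction) even though the optimum is identical; always certify point
  estimates with the variability check.
* The tabular (TSV) dialect preserves the network, bounds, genes, EC,
  subsystem and kind, but not metabolite formulae or compartment names
  beyond id suffixes; JSON and SBML are the lossless dialects.
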