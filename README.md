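# diatomgem

Constraint-based metabolic modelling for compartmentalized photoautotrophs,
built around the analyses used to characterize diatom genome-scale
reconstructions: model quality control, flux balance analysis with
total-flux minimization, silica-limitation and maintenance-energy scans,
reaction essentiality, and maximum-theoretical-yield screening of native and
heterologous products.

## Who this is for

Researchers working with stoichiometric reconstructions of photosynthetic
eukaryotes — in particular diatoms, whose silica frustule couples growth to
silicic-acid uptake and whose chloroplast–mitochondrion energetics (the
malate–oxaloacetate valve, linear vs cyclic photosynthetic electron flow)
shape every flux prediction. The package reads and writes SBML Level 3
(+fbc), a native JSON dialect, and flat TSV reaction listings, and ships a
deterministic synthetic three-compartment photoautotroph ("minidiatom",
76 reactions) on which the entire pipeline runs without any external data.

## The model

A metabolic state is a flux vector **v** (mmol · gDCW⁻¹ · h⁻¹) satisfying
steady state and bounds:

```
S · v = 0,   lb ≤ v ≤ ub
```

where S is the stoichiometric matrix. Photoautotrophic simulations fix the
growth rate and the non-growth ATP maintenance and minimize the total
cellular flux:

```
min Σᵢ |vᵢ|   subject to   S·v = 0,  v_biomass = t,  v_ATPM = m
```

solved as an LP by splitting each flux into non-negative forward/reverse
components (scipy/HiGHS). Because pFBA optima can be degenerate,
`fixed_objective_variability` computes per-reaction flux ranges at the
optimum; a range width ≤ 1e-6 certifies a uniquely determined flux before it
is reported as a point estimate.

Yields are reported as x = v_product / v_CO₂ (mol product per mol CO₂) with
growth constrained to a fraction of the wild-type rate; a reaction is
*essential* when pinning its flux to zero makes the fixed-growth LP
infeasible.

## Worked example

```python
from diatomgem import build_toy_photoautotroph, pfba, SimulationConstraints

model, manifest = build_toy_photoautotroph()
sol = pfba(model, SimulationConstraints(growth=0.024, atpm=1.5))
print(f"CO2 uptake     {sol['EX_co2']:.3f}")
print(f"photon uptake  {sol['EX_photon']:.3f}")
print(f"O2 evolution   {sol['EX_o2']:.3f}")
print(f"CEF flux       {sol[manifest.reaction('CEF')]:.3f}")
```

prints

```
CO2 uptake     0.948
photon uptake  12.351
O2 evolution   1.253
CEF flux       0.000
```

At the measured growth rate (0.024 h⁻¹) and low maintenance
(1.5 mmol/(gDCW·h)) the toy diatom fixes ~0.95 mmol CO₂ per gDCW per hour
using ~12.4 photons, evolves O₂ at 1.32× the CO₂ uptake, and runs **linear
electron flow only** — cyclic electron flow carries zero flux (and the flux
variability check certifies that zero is the only optimal value). Knocking
out the mitochondrial malate–oxaloacetate antiporter at high maintenance
(`shuttle_knockout_experiment(model, atpm=7.5)`) activates cyclic electron
flow and raises photon demand; re-pinning the photon uptake at its wild-type
value then makes the problem infeasible — the valve is how the chloroplast
balances its ATP/NADPH budget.

The same model drives the command line:

```
diatomgem build-toy --out toy.json
diatomgem validate toy.json              # elemental balance, leaks, gaps
diatomgem simulate toy.json --check-unique cef
diatomgem scan-si toy.json               # biomass vs chrysolaminarin trade-off
diatomgem yields toy.json --product mal_m --module isobutanol
```

## Layout

| module | contents |
|---|---|
| `diatomgem.core` | model containers, formulae, SBML/JSON/TSV I/O, S matrix |
| `diatomgem.synthetic` | toy photoautotroph generator, biomass-equation builder |
| `diatomgem.qc` | elemental balance, energy-leak probes, gap find/fill |
| `diatomgem.fba` | FBA, total-flux minimization, variability at the optimum |
| `diatomgem.analyses` | essentiality, Si/ATPM scans, valve knockout, yields |
| `diatomgem.compare` | EC-based model comparison, carbon partition, summaries |
| `diatomgem.cli` | `diatomgem` command-line entry point |

See `docs/methods.md` for the modelling assumptions, parameter defaults, and
known limitations.
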