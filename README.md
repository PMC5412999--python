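# ionex

Strict charge-neutral, multi-site ion-exchange modeling of ion adsorption
envelopes on mineral surfaces — built around the competitive retention of
H⁺, Na⁺, Cl⁻ and phthalate (L²⁻) on goethite (α-FeOOH).

## The problem

Adsorption envelopes report how much of each ion a suspended mineral holds
as a function of equilibrium pH. Most mechanistic treatments invoke surface
charge: intrinsic constants, diffuse layers, charge-distribution terms. The
strict ion-exchange alternative modeled here assumes instead that **every
surface reaction is charge-neutral** — an adsorbing ion always brings a
counter-ion along or displaces a like charge — so no charged surface species
and no electrostatic corrections exist anywhere in the model. Each surface
site class S carries a fixed total density Γ_max that is always fully
partitioned among its species:

```
SOH + H⁺ + Cl⁻ ⇌ SOH₂Cl                 K = {SOH₂Cl} / ({SOH}[H⁺][Cl⁻])
SOH + Na⁺      ⇌ SONa + H⁺              K = {SONa}[H⁺] / ({SOH}[Na⁺])
2SOH + 2H⁺ + L²⁻ ⇌ (SOH₂)₂L             K = {(SOH₂)₂L} / ({SOH}²[H⁺]²[L²⁻])

Γ_max = {SOH} + {SOH₂Cl} + {SONa} + 2{(SOH₂)₂L}      (per site class)
```

All constants are concentration-basis (pK = −log₁₀K); pH is the measured
value of each batch, never a solved unknown, and "proton adsorption" is the
stoichiometric proton content of the surface complexes. A crucial piece of
bookkeeping is that pH adjustment itself feeds the competition: every mmol
of HCl used to lower pH adds a mmol of Cl⁻, which at low pH competes the
divalent anion off the surface.

## What the package does

- `ionex.chemistry` — model types (sites, exchange reactions, aqueous
  reactions), validation of the charge-neutrality contract, unit
  conversions (Γ ↔ mmol/L), ΔG° = RT ln10 · pK, and equivalence transforms
  between reaction formulations (H⁺ uptake ↔ OH⁻ release differs by pK_w;
  half-reaction scaling halves the pK). YAML/JSON model files.
- `ionex.speciation` — aqueous speciation at fixed pH (diprotic phthalate,
  NaL⁻ ion pair, hydroxide).
- `ionex.solver` — the coupled surface+solution equilibrium per condition
  (damped Newton on log concentrations with analytic Jacobian), envelope
  prediction, derived proton adsorption.
- `ionex.conditions` — titration schedules → per-condition totals
  (conjugate-ion accounting), dataset CSV I/O, published data offsets.
- `ionex.fitting` — single-datum closed-form pK solves, staged/tied
  least-squares pK optimization, R².
- `ionex.scenarios` — runnable transcriptions of the published simulation
  scenarios and model tables, plus a synthetic-envelope generator with
  Gaussian noise for parameter-recovery studies.
- `ionex.cli` — `ionex simulate | speciate | conditions | fit | synth`.

## Worked example

```python
from ionex import Condition, load_scenario, solve_equilibrium
from ionex.scenarios import SIMULATION_GEOMETRY

model = load_scenario("fig2_fixedCl").model   # bidentate L (pK -18.7) vs Cl (pK -8)
cond = Condition(id="p", pH=3.0, totals={"L": 1e-3, "Cl": 4.54e-3},
                 geometry=SIMULATION_GEOMETRY)
res = solve_equilibrium(model, cond)
print(f"{res.adsorbed['L']:.3f} {res.adsorbed['Cl']:.3f} {res.adsorbed['H']:.3f}")
```

prints `0.720 0.558 1.999` — at pH 3 the 2.0 µmol/m² site pool splits
between phthalate (0.72 µmol/m², two sites each) and chloride
(0.56 µmol/m², one site each), and the derived proton uptake
2·Γ_L + Γ_Cl sits at the site total: the two anions exchange places in
charge-neutral proportion while proton adsorption stays flat. Remove the
chloride and the phthalate plateau rises to 1.0 µmol/m² (= capacity/2).

The `examples/` directory has one short script per capability
(formulation comparison, chloride competition, speciation, titrant
accounting, synthetic-data pK recovery); each prints the numbers it
computes with a line on what they mean.

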