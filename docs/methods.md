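# Methods

## Model

A strict charge-neutral ion-exchange model consists of:

- **Surface sites.** Each site class `s` (goethite's crystallographic
  hydroxyl environments Sa–Sd) has a density Γ_max (µmol/m²), converted to a
  volumetric capacity `cap = Γ_max · A · c_s` (mol/L) with `A` the specific
  surface area (m²/g) and `c_s` the solids concentration (g/L). The capacity
  is a hard constraint: bare SOH plus all complexes (weighted by the number
  of sites each occupies) always sum to it.
- **Surface reactions.** `n_soh SOH + Σ ν_i C_i ⇌ pc · P` with signed
  coefficients ν (negative = released, as the proton released by Na⁺/H⁺
  exchange). The product must be net charge-neutral — validated from the
  component charges — which is the theory's defining restriction. The
  mass-action law is evaluated on a concentration basis,
  `{P} = (K · {SOH}^n_soh · Π[C_i]^ν_i)^(1/pc)`, with `K = 10^(−pK)`.
  The product coefficient `pc` supports equivalent "half-reaction"
  formulations: scaling a reaction by ½ halves its pK while describing the
  same physical species, so predictions are unchanged (K_full = K_half²).
  This is distinct from a genuinely different half-occupancy species, which
  is written as its own reaction with `pc = 1`.
- **Aqueous reactions.** Formation of complexes from components
  (`HL⁻`, `H₂L` from the phthalate acidity constants pKa 2.95/4.9 as
  formation log K of 4.9 and 7.85; the NaL⁻ pair with log K 0.7). H⁺ and
  OH⁻ are built-in components whose concentrations are fixed by pH and
  pK_w (default 14.0 at 20 °C; configurable), never solved.

No activity corrections are applied: the theory is stated, and fitted, on
molar concentrations, and the ionic strengths involved (0.15–5 mM) keep
activity coefficients near unity. Temperature enters only the ΔG° reporting
helper (ΔG° = RT ln10 · pK); equilibrium constants are treated as isothermal
constants at 20 °C.

## Equilibrium solver

Unknowns are natural logs of the free concentrations of the components with
nonzero totals plus log {SOH} per site; pH-fixed species fold into the
mass-action prefactors. Every species is then a pure power law of the
unknowns, and the content matrix that builds the mass balances is the same
matrix that appears in the exponents. The resulting Jacobian,
`diag(free) + Aᵀ diag(species) A`, is symmetric positive semidefinite, and a
damped Newton iteration (backtracking line search on the relative residual
norm, step clipped at 8 log units) converges in a handful of iterations
across the full pH 2–11 range and pK values spanning ±20. Tolerances:
relative residual ∞-norm < 1e-12, at most 200 iterations; on a singular or
stalled step the solver falls back to scipy's hybrid Powell root finder.
Initialization is free = totals, {SOH} = capacity. Site conservation and
component mass balances are re-asserted on every returned solution (at
1e-9 relative), not assumed.

Degenerate inputs: components with zero total are eliminated (their species
cannot form); a surface reaction that would *release* a zero-total
component is a configuration error; zero-capacity sites are rejected.

Proton adsorption is derived, not solved: each complex contributes its net
proton content (consumed H⁺ minus consumed OH⁻, per product unit) times its
concentration, with bare SOH the zero reference. Positive values mean
proton uptake (low pH); alignment of measured back-titration data to this
reference is the offset machinery's job, with the published corrections
(+0.50 µmol/m² on protons, +0.11 µmol/m² and +0.011 mM on chloride) applied
once and recorded — a second application is refused. Offsets are *added* to
raw values; the sign convention is chosen so a proton curve reading zero at
the point of zero salt effect moves to its stoichiometric value.

## Titrant accounting

Totals per condition are background electrolyte + fixed additions +
conjugate ions from the titrant (Cl⁻ from HCl, Na⁺ from NaOH), in mol/L of
the 35 mL final volume. Acid and base are never both dosed to one
condition. The synthetic schedule generator emulates a real titration: the
dose needed to reach pH p is the free acid/base relative to the zero point
of titration plus a sigmoidal surface proton demand (scale: the 4.4 µmol/m²
total site pool, centered at pH 4.5) plus, when phthalate is present, the
diprotic buffer demand computed from the closed-form α-fractions. This
reproduces the magnitudes of the real experiments (total Cl⁻ of a few mM at
pH 2.3 over a 0.15 mM NaCl background) without claiming their exact values.

## Scenarios and synthetic data

Shipped scenarios transcribe the published simulation captions and model
tables (single-formulation comparisons; the fixed/variable/zero-chloride
competitive simulations; the four-site chloride model; the four-site
competitive phthalate model with three sites tied to one phthalate pK).
For the variable-chloride simulation only two anchors are printed
(1.27 mM above pH 3.18, 4.54 mM at pH 2.33); total Cl⁻ is interpolated
linearly in pH between them and extrapolated below.

The synthetic generator forward-predicts a model over a schedule and adds
iid Gaussian noise per ion (default σ = 0.05 µmol/m² on a 28-point grid,
pH 2.3–10.4, matching the experiments' span and scatter scale; chloride
scatter in the real data is visibly larger than phthalate's, so per-ion σ
is configurable). σ = 0 reproduces predictions bit-for-bit and a fixed seed
reproduces datasets exactly. What passing recovery tests on these data show
is that the estimation machinery is consistent and calibrated under the
model's own assumptions — iid Gaussian errors, exactly known totals and
geometry; they do not show robustness to the structured errors of real
envelopes (electrode drift, back-titration bias, correlated Cl⁻ scatter).

## Fitting

`solve_single_point_pK` inverts the mass-action law through one
(pH, Γ) datum in closed form after feasibility checks against the
saturation limit. Because Γ (µmol/m²) and capacity (mmol/L) live on
different scales, the conversion uses an `area_per_liter` argument
(default 100 m²/L, the idealized loading where 2.0 µmol/m² ≡ 0.2 mmol/L).

`fit_pks` runs an ordered list of stages. Each stage frees a few pKs —
a tie group (e.g. the three sites sharing one phthalate pK) moves as a
single parameter; reactions marked `fixed` (the "estimated" high-pH sodium
constants) can never be freed — and minimizes the unweighted sum of squared
Γ residuals (µmol/m²; per-ion weights available) over its pH window and ion
subset, holding all other constants. The optimizer is a bounded
derivative-free local search (Brent on one parameter, Powell otherwise)
started deterministically at the incoming values, with bounds
[−30, 15] by default; a stage can never leave the objective worse than it
found it. Being local is deliberate — the staged procedure mirrors how the
model is assembled from the data features each constant controls — but it
means a stage started far from truth against a window dominated by other
reactions, or two near-identical site capacities freed jointly from a
distant start, can settle on a compensating or label-swapped local minimum.
Windows should bracket the feature their parameter controls.

R² is reported per ion over the full dataset; windowed reporting (e.g.
protons above pH 3.5 only) is available by filtering the residual table.

## Known limitations

- Concentration basis only; no ionic-strength correction (inappropriate
  above ~10 mM without one).
- pH is always an input; titration-path simulation (solve for pH given
  added acid) is out of scope.
- No uncertainty intervals on fitted pKs; the staged optimizer is local.
- The raw measured envelopes behind the published four-site fits exist only
  as PDF supplements and are not redistributed; the corresponding R²
  verification runs only if transcriptions are supplied under `data/`.
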