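"""Parameter recovery: fit a site pK from a noisy synthetic envelope.

Generates a synthetic chloride/proton adsorption envelope from the four-site
goethite model (Gaussian noise, 0.05 umol/m^2), perturbs one chloride pK,
and recovers it by windowed least squares — the same staged procedure used
to build the model from real envelope data.
"""

from ionex import FitPlan, FitStage, NoiseModel, fit_pks, generate_synthetic_envelope, load_scenario

scenario = load_scenario("table1_goethite")
truth = {r.product: r.pK for r in scenario.model.surface_reactions}

dataset = generate_synthetic_envelope(
    scenario.model, scenario.schedule, [c.pH for c in scenario.conditions],
    NoiseModel(sigma=0.05, seed=42),
    ions=["H", "Cl", "Na"],  # the ions this chloride-system model predicts
)

start = scenario.model.model_copy(update={"surface_reactions": [
    r.model_copy(update={"pK": r.pK + 0.5}) if r.product == "ScOH2Cl" else r
    for r in scenario.model.surface_reactions]})

plan = FitPlan(stages=[FitStage(free=["ScOH2Cl"], window=(3.0, 5.5), ions=["Cl"])])
result = fit_pks(start, dataset, plan)

print(f"true pK(ScOH2Cl)      = {truth['ScOH2Cl']:+.2f}")
print(f"start (perturbed)     = {truth['ScOH2Cl'] + 0.5:+.2f}")
print(f"recovered             = {result.pks['ScOH2Cl']:+.3f}")
print(f"R^2 over full dataset = " + ", ".join(
    f"{ion}: {r2:.3f}" for ion, r2 in sorted(result.r2.items())))
print("\nWith 0.05 umol/m^2 noise on 28 conditions the pK comes back within")
print("a few hundredths; residual R^2 < 1 reflects the injected noise only.")
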