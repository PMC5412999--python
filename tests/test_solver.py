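import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionex import (
    Condition,
    ExchangeReaction,
    ModelSpec,
    SolverError,
    SurfaceSite,
    formulation_shift,
    predict_envelope,
    predict_proton_adsorption,
    solve_equilibrium,
)
from ionex.scenarios import COMPONENTS, SIMULATION_GEOMETRY

from conftest import condition, single_site_cl_model


def quadratic_complex(k: float, cap: float, total: float) -> float:
    """Closed-form oracle: smaller root of k a^2 - (k (cap+total) + 1) a + k cap total,
    in the rationalized form that avoids cancellation for weak binding."""
    b = k * (cap + total) + 1.0
    disc = b * b - 4.0 * k * k * cap * total
    return 2.0 * k * cap * total / (b + math.sqrt(disc))


class TestSingleReactionOracle:
    def test_printed_quadratic_case(self, cl_model):
        # pK -8 at pH 4 with 0.2 mM sites and 1.0 mM Cl: 1e4 a^2 - 13 a + 2e-3 = 0
        res = solve_equilibrium(cl_model, condition(4.0, {"Cl": 1e-3}))
        complex_conc = res.surface[("S", "SOH2Cl")]
        assert complex_conc == pytest.approx(1.7830e-4, abs=1e-8)
        assert res.adsorbed["Cl"] == pytest.approx(1.78301, abs=1e-4)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        pk=st.floats(-12.0, -2.0),
        ph=st.floats(2.0, 10.0),
        total=st.floats(1e-5, 1e-2),
        gamma_max=st.floats(0.1, 5.0),
    )
    def test_matches_quadratic_closed_form(self, pk, ph, total, gamma_max):
        model = single_site_cl_model(pk=pk, gamma_max=gamma_max)
        res = solve_equilibrium(model, condition(ph, {"Cl": total}))
        k_eff = 10.0 ** (-pk) * 10.0 ** (-ph)
        cap = gamma_max * 1e-4  # 100 m^2/L loading
        expected = quadratic_complex(k_eff, cap, total)
        assert res.surface[("S", "SOH2Cl")] == pytest.approx(expected, rel=1e-8)


class TestLimitsAndConservation:
    def test_no_binding_means_no_adsorption(self, cl_model):
        inert = cl_model.model_copy(update={"surface_reactions": [
            r.model_copy(update={"pK": 30.0}) for r in cl_model.surface_reactions
        ]})
        res = solve_equilibrium(inert, condition(4.0, {"Cl": 1e-3}))
        assert res.adsorbed["Cl"] == pytest.approx(0.0, abs=1e-10)
        assert res.free["Cl"] == pytest.approx(1e-3, rel=1e-10)

    @pytest.mark.parametrize("ph", [2.0, 3.0, 4.5, 6.0, 8.0, 11.0])
    def test_site_and_mass_conservation(self, fig2_fixed, ph):
        cond = condition(ph, {"L": 1e-3, "Cl": 4.54e-3})
        res = solve_equilibrium(fig2_fixed.model, cond)
        cap = 2e-4
        occupied = res.soh["Sa"] + res.surface[("Sa", "SaOH2Cl")] \
            + 2 * res.surface[("Sa", "(SaOH2)2L")]
        assert occupied == pytest.approx(cap, rel=1e-10)
        bound_l = res.surface[("Sa", "(SaOH2)2L")]
        assert res.free["L"] + bound_l == pytest.approx(1e-3, rel=1e-10)
        bound_cl = res.surface[("Sa", "SaOH2Cl")]
        assert res.free["Cl"] + bound_cl == pytest.approx(4.54e-3, rel=1e-10)

    def test_mass_action_law_holds(self, fig2_fixed):
        res = solve_equilibrium(fig2_fixed.model, condition(3.0, {"L": 1e-3, "Cl": 4.54e-3}))
        h = 1e-3
        k7 = res.surface[("Sa", "(SaOH2)2L")] / (
            res.soh["Sa"] ** 2 * h ** 2 * res.free["L"])
        assert math.log10(k7) == pytest.approx(18.7, abs=1e-9)

    def test_determinism(self, fig2_fixed):
        cond = condition(5.0, {"L": 1e-3, "Cl": 4.54e-3})
        a = solve_equilibrium(fig2_fixed.model, cond)
        b = solve_equilibrium(fig2_fixed.model, cond)
        assert a.adsorbed == b.adsorbed


class TestCompetitivePlateaus:
    def test_fixed_chloride_plateau(self, fig2_fixed):
        res = solve_equilibrium(fig2_fixed.model, condition(3.0, {"L": 1e-3, "Cl": 4.54e-3}))
        assert res.adsorbed["L"] == pytest.approx(0.722, abs=0.005)
        assert res.adsorbed["Cl"] == pytest.approx(0.556, abs=0.005)

    def test_chloride_free_plateau(self, fig2_free):
        env = predict_envelope(fig2_free.model, fig2_free.conditions)
        low = env[env.pH < 4.0]
        assert low.gamma_L.max() == pytest.approx(1.0, abs=2e-3)
        assert (env[env.pH <= 3.0].gamma_L > 0.999).all()
        assert (low.gamma_L <= 1.0 + 1e-9).all()

    def test_fixed_cl_curve_is_scaled_down_not_shifted(self, fig2_fixed, fig2_free):
        env_fixed = predict_envelope(fig2_fixed.model, fig2_fixed.conditions)
        env_free = predict_envelope(fig2_free.model, fig2_free.conditions)
        plateau_ratio = env_fixed.gamma_L.max() / env_free.gamma_L.max()
        assert plateau_ratio == pytest.approx(0.722 / 1.0, abs=0.01)
        # the half-maximum pH (edge position) must not move
        def edge(env):
            half = env.gamma_L.max() / 2
            above = env[env.gamma_L >= half]
            return above.pH.max()
        assert abs(edge(env_fixed) - edge(env_free)) <= 0.25


class TestProtonAdsorption:
    @pytest.mark.parametrize("ph", [3.0, 4.0, 5.0, 6.0])
    def test_chloride_only_one_to_one(self, cl_model, ph):
        res = solve_equilibrium(cl_model, condition(ph, {"Cl": 1e-3}))
        assert res.adsorbed["H"] == pytest.approx(res.adsorbed["Cl"], rel=1e-12)

    def test_fig2_plateau_stoichiometry(self, fig2_fixed):
        res = solve_equilibrium(fig2_fixed.model, condition(3.0, {"L": 1e-3, "Cl": 4.54e-3}))
        expected = 2 * res.adsorbed["L"] + res.adsorbed["Cl"]
        assert res.adsorbed["H"] == pytest.approx(expected, rel=1e-12)
        assert res.adsorbed["H"] == pytest.approx(2.0, abs=0.01)

    def test_sodium_exchange_releases_protons(self):
        model = ModelSpec(
            sites=[SurfaceSite(name="S", gamma_max=2.0)],
            components=COMPONENTS,
            surface_reactions=[ExchangeReaction(
                site="S", n_soh=1, consumed={"Na": 1, "H": -1},
                product="SONa", occupancy=1, pK=6.8)],
            geometry=SIMULATION_GEOMETRY,
        )
        res = solve_equilibrium(model, condition(9.0, {"Na": 1e-3}))
        assert res.adsorbed["Na"] > 0.01
        assert res.adsorbed["H"] == pytest.approx(-res.adsorbed["Na"], rel=1e-12)


class TestEnvelope:
    def test_rows_sorted_and_deterministic(self, cl_model):
        conds = [condition(ph, {"Cl": 1e-3}, cid=f"c{i}")
                 for i, ph in enumerate([6.0, 3.0, 3.0, 4.5])]
        env = predict_envelope(cl_model, conds)
        assert list(env.pH) == sorted(env.pH)
        dup = env[env.pH == 3.0]
        assert dup.gamma_Cl.nunique() == 1  # identical rows for duplicated condition

    def test_anion_coadsorption_monotone_in_ph(self, cl_model):
        conds = [condition(ph, {"Cl": 1e-3}, cid=f"c{i}")
                 for i, ph in enumerate(np.linspace(2, 11, 19))]
        env = predict_envelope(cl_model, conds)
        assert (np.diff(env.gamma_Cl) <= 1e-12).all()

    def test_competition_never_helps_the_other_ion(self, fig2_free, fig2_fixed):
        conds = [condition(ph, {"L": 1e-3, "Cl": 4.54e-3}, cid=f"c{i}")
                 for i, ph in enumerate(np.linspace(2, 11, 10))]
        alone = predict_envelope(fig2_free.model, conds)
        compete = predict_envelope(fig2_fixed.model, conds)
        assert (compete.gamma_L <= alone.gamma_L + 1e-9).all()

    def test_empty_conditions_rejected(self, cl_model):
        with pytest.raises(ValueError):
            predict_envelope(cl_model, [])

    def test_solver_error_carries_condition_id(self, cl_model):
        bad = cl_model.model_copy(update={"sites": []})
        with pytest.raises(Exception):
            predict_envelope(bad, [condition(4.0, {"Cl": 1e-3}, cid="offender")])


class TestFormulationEquivalence:
    @pytest.mark.parametrize("variant", ["hydroxide-release", "half-reaction"])
    def test_shifted_model_predicts_identically(self, fig2_free, variant):
        model = fig2_free.model
        shifted = model.model_copy(update={"surface_reactions": [
            formulation_shift(model.surface_reactions[0], variant)
        ]})
        env_a = predict_envelope(model, fig2_free.conditions)
        env_b = predict_envelope(shifted, fig2_free.conditions)
        assert np.abs(env_a.gamma_L - env_b.gamma_L).max() < 1e-8
        assert np.abs(env_a.gamma_H - env_b.gamma_H).max() < 1e-8
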