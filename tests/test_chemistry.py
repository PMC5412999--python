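import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from ionex import (
    AqueousComponent,
    AqueousReaction,
    ExchangeReaction,
    GeometryContext,
    ModelSpec,
    SurfaceSite,
    formulation_shift,
    gamma_max_from_capacity,
    gibbs_free_energy,
    model_from_json,
    model_from_yaml,
    model_to_json,
    model_to_yaml,
    site_capacity_molar,
)
from ionex.scenarios import COMPONENTS


class TestSiteCapacity:
    @pytest.mark.parametrize(
        "gamma,area,solids,expected",
        [
            (2.0, 100.0, 1.0, 0.2),          # 2.0 umol/m^2 on 100 m^2/L
            (0.0, 100.0, 1.0, 0.0),
            (4.4, 29.50, 3.43, 0.4452140),   # the full goethite site pool
        ],
    )
    def test_values(self, gamma, area, solids, expected):
        geom = GeometryContext(surface_area=area, solids_conc=solids)
        assert site_capacity_molar(gamma, geom) == pytest.approx(expected, rel=1e-6)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        gamma=st.floats(1e-3, 1e3),
        area=st.floats(1e-2, 1e3),
        solids=st.floats(1e-2, 1e2),
    )
    def test_round_trip(self, gamma, area, solids):
        geom = GeometryContext(surface_area=area, solids_conc=solids)
        back = gamma_max_from_capacity(site_capacity_molar(gamma, geom), geom)
        assert back == pytest.approx(gamma, rel=1e-12)

    def test_negative_rejected(self):
        geom = GeometryContext(surface_area=100.0, solids_conc=1.0)
        with pytest.raises(ValueError):
            site_capacity_molar(-1.0, geom)
        with pytest.raises(ValidationError):
            GeometryContext(surface_area=-1.0, solids_conc=1.0)


class TestGibbs:
    def test_zero_pk_is_zero(self):
        assert gibbs_free_energy(0.0, 293.15) == 0.0

    def test_strong_binding_value(self):
        # dG = RT ln(10) pK: -18.72 at 20 C is about -105.1 kJ/mol
        assert gibbs_free_energy(-18.72, 293.15) == pytest.approx(-105.06, abs=0.05)

    @pytest.mark.parametrize("pk", [-5.0, -0.1, 0.3, 12.0])
    def test_sign_follows_pk(self, pk):
        assert math.copysign(1, gibbs_free_energy(pk)) == math.copysign(1, pk)

    def test_bad_temperature(self):
        with pytest.raises(ValueError):
            gibbs_free_energy(1.0, temperature=0.0)


def _cl_reaction(pk=-8.0):
    return ExchangeReaction(site="S", n_soh=1, consumed={"H": 1, "Cl": 1},
                            product="SOH2Cl", occupancy=1, pK=pk)


def _bidentate(pk=-18.72):
    return ExchangeReaction(site="S", n_soh=2, consumed={"H": 2, "L": 1},
                            product="(SOH2)2L", occupancy=2, pK=pk)


class TestFormulationShift:
    def test_hydroxide_release_shifts_by_pkw(self):
        shifted = formulation_shift(_cl_reaction(-8.0), "hydroxide-release", pkw=14.0)
        assert shifted.pK == pytest.approx(-8.0 + 14.0)
        assert shifted.consumed == {"Cl": 1, "OH": -1}

    def test_hydroxide_release_na_exchange(self):
        # SOH + Na+ <=> SONa + H+  becomes  SOH + OH- + Na+ <=> SONa + H2O
        rxn = ExchangeReaction(site="S", n_soh=1, consumed={"Na": 1, "H": -1},
                               product="SONa", occupancy=1, pK=8.8)
        shifted = formulation_shift(rxn, "hydroxide-release")
        assert shifted.consumed == {"Na": 1, "OH": 1}
        assert shifted.pK == pytest.approx(8.8 - 14.0)

    def test_half_reaction_halves_pk(self):
        half = formulation_shift(_bidentate(-18.72), "half-reaction")
        assert half.pK == pytest.approx(-9.36)
        assert half.n_soh == 1
        assert half.consumed == {"H": 1, "L": 0.5}
        assert half.product_coeff == 0.5
        assert half.occupancy == 2  # same physical species

    @pytest.mark.parametrize("variant,inverse", [
        ("hydroxide-release", "hydroxide-release"),
        ("half-reaction", "double"),
    ])
    def test_shift_round_trips(self, variant, inverse):
        original = _bidentate()
        back = formulation_shift(formulation_shift(original, variant), inverse)
        assert back.pK == pytest.approx(original.pK)
        assert back.consumed == original.consumed
        assert back.n_soh == original.n_soh

    def test_inapplicable_variant(self):
        no_proton = ExchangeReaction(site="S", n_soh=1, consumed={"Na": 1, "Cl": 1},
                                     product="SNaCl", occupancy=1, pK=1.0)
        with pytest.raises(ValueError):
            formulation_shift(no_proton, "hydroxide-release")
        with pytest.raises(ValueError):
            formulation_shift(_cl_reaction(), "no-such-variant")


class TestModelValidation:
    def _spec(self, reactions, sites=None):
        return ModelSpec(
            sites=sites or [SurfaceSite(name="S", gamma_max=2.0)],
            components=COMPONENTS,
            surface_reactions=reactions,
        )

    def test_valid_model_builds(self):
        spec = self._spec([_cl_reaction(), _bidentate()])
        assert len(spec.surface_reactions) == 2

    def test_charged_surface_complex_rejected(self):
        # bare proton adsorption would make SOH2+, which the theory forbids
        charged = ExchangeReaction(site="S", n_soh=1, consumed={"H": 1},
                                   product="SOH2", occupancy=1, pK=-5.0)
        with pytest.raises(ValidationError, match="neutral"):
            self._spec([charged])

    def test_unknown_site_rejected(self):
        bad = ExchangeReaction(site="Sx", n_soh=1, consumed={"H": 1, "Cl": 1},
                               product="SxOH2Cl", occupancy=1, pK=-5.0)
        with pytest.raises(ValidationError, match="unknown site"):
            self._spec([bad])

    def test_duplicate_site_names_rejected(self):
        with pytest.raises(ValidationError, match="unique"):
            self._spec([], sites=[SurfaceSite(name="S", gamma_max=1.0),
                                  SurfaceSite(name="S", gamma_max=2.0)])

    def test_occupancy_stoichiometry_contract(self):
        with pytest.raises(ValidationError, match="occupancy"):
            ExchangeReaction(site="S", n_soh=2, consumed={"H": 2, "L": 1},
                             product="(SOH2)2L", occupancy=1, pK=-18.0)

    def test_aqueous_charge_balance_checked(self):
        bad = AqueousReaction(product="HL", stoichiometry={"H": 1, "L": 1},
                              logk=4.9, charge=0)  # should be -1
        with pytest.raises(ValidationError, match="charge"):
            ModelSpec(sites=[SurfaceSite(name="S", gamma_max=1.0)],
                      components=COMPONENTS,
                      surface_reactions=[], aqueous_reactions=[bad])


class TestSerialization:
    def _model(self):
        return ModelSpec(
            sites=[SurfaceSite(name="S", gamma_max=2.0)],
            components=COMPONENTS,
            surface_reactions=[_cl_reaction(), _bidentate()],
            aqueous_reactions=[AqueousReaction(product="HL",
                                               stoichiometry={"H": 1, "L": 1},
                                               logk=4.9, charge=-1)],
            geometry=GeometryContext(surface_area=29.5, solids_conc=3.43),
        )

    def test_yaml_round_trip(self, tmp_path):
        model = self._model()
        path = tmp_path / "model.yaml"
        model_to_yaml(model, path)
        assert model_from_yaml(str(path)) == model

    def test_json_round_trip(self):
        model = self._model()
        assert model_from_json(model_to_json(model)) == model

    def test_unsupported_schema_version(self):
        text = model_to_yaml(self._model()).replace("schema_version: 1",
                                                    "schema_version: 99")
        with pytest.raises(ValueError, match="schema version"):
            model_from_yaml(text)
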