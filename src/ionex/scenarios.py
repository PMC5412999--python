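"""Built-in scenarios and the synthetic-envelope generator.

The scenarios are self-contained transcriptions of the published simulation
captions and model tables for phthalate/chloride adsorption on goethite:

* ``fig1_eq6`` / ``fig1_eq7`` / ``fig1_eq8`` — the three rival formulations
  of the 2:1 H:phthalate surface reaction, each pinned through the single
  datum (pH 6, 0.5 umol/m^2).
* ``fig2_noCl`` / ``fig2_fixedCl`` / ``fig2_variableCl`` — the competitive
  chloride/phthalate simulations on one 2.0 umol/m^2 site.
* ``table1_goethite`` — the four-site Cl-/Na+/H+ exchange model.
* ``table2_goethite_phthalate`` — the four-site competitive model with
  phthalate (three sites tied to one phthalate pK) and aqueous phthalate
  protonation plus the Na-phthalate ion pair.

``generate_synthetic_envelope`` emulates the batch experiments (35 mL final
volume, 3.43 g/L goethite at 29.5 m^2/g) by forward-predicting a model over
a titration schedule and adding iid Gaussian measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel, Field

from .chemistry import (
    AqueousComponent,
    AqueousReaction,
    ExchangeReaction,
    GeometryContext,
    ModelSpec,
    SurfaceSite,
)
from .conditions import (
    EnvelopeDataset,
    Titrant,
    TitrantDose,
    TitrationSchedule,
    build_conditions,
)
from .solver import Condition, predict_envelope
from .speciation import diprotic_fractions

__all__ = [
    "Scenario",
    "NoiseModel",
    "SCENARIO_NAMES",
    "load_scenario",
    "generate_synthetic_envelope",
    "default_titration_schedule",
    "GOETHITE_GEOMETRY",
    "SIMULATION_GEOMETRY",
]

#: measured goethite loading of the batch experiments
GOETHITE_GEOMETRY = GeometryContext(surface_area=29.50, solids_conc=3.43)

#: idealized loading of the illustrative simulations: 100 m^2/L, so a
#: 2.0 umol/m^2 site density is exactly 0.2 mmol/L of sites
SIMULATION_GEOMETRY = GeometryContext(surface_area=100.0, solids_conc=1.0)

#: phthalate acidity constants (pKa1 = 2.95, pKa2 = 4.9)
PHTHALATE_PKA = (2.95, 4.9)

COMPONENTS = [
    AqueousComponent(name="Na", charge=1),
    AqueousComponent(name="Cl", charge=-1),
    AqueousComponent(name="L", charge=-2),
]

#: aqueous formation reactions from (H, Na, L) components: HL- and H2L from
#: the acidity constants, NaL- ion pair with formation pK -0.7 (logK 0.7)
PHTHALATE_AQUEOUS = [
    AqueousReaction(product="HL", stoichiometry={"H": 1, "L": 1},
                    logk=PHTHALATE_PKA[1], charge=-1),
    AqueousReaction(product="H2L", stoichiometry={"H": 2, "L": 1},
                    logk=PHTHALATE_PKA[0] + PHTHALATE_PKA[1], charge=0),
    AqueousReaction(product="NaL", stoichiometry={"Na": 1, "L": 1},
                    logk=0.7, charge=-1),
]


def _cl_reaction(site: str, pk: float) -> ExchangeReaction:
    # SOH + H+ + Cl- <=> SOH2Cl
    return ExchangeReaction(site=site, n_soh=1, consumed={"H": 1, "Cl": 1},
                            product=f"{site}OH2Cl", occupancy=1, pK=pk)


def _na_reaction(site: str, pk: float, fixed: bool = False) -> ExchangeReaction:
    # SOH + Na+ <=> SONa + H+
    return ExchangeReaction(site=site, n_soh=1, consumed={"Na": 1, "H": -1},
                            product=f"{site}ONa", occupancy=1, pK=pk, fixed=fixed)


def _l_reaction(site: str, pk: float, tie: Optional[str] = None) -> ExchangeReaction:
    # 2 SOH + 2 H+ + L2- <=> (SOH2)2L
    return ExchangeReaction(site=site, n_soh=2, consumed={"H": 2, "L": 1},
                            product=f"({site}OH2)2L", occupancy=2, pK=pk,
                            tie_group=tie)


class NoiseModel(BaseModel):
    """Gaussian measurement scatter on surface densities, per ion."""

    sigma: Union[float, Dict[str, float]] = 0.05  # umol/m^2
    seed: int = 0

    def sigma_for(self, ion: str) -> float:
        if isinstance(self.sigma, dict):
            return self.sigma.get(ion, 0.0)
        return self.sigma


@dataclass
class Scenario:
    """A self-contained, runnable model + conditions with documented anchors."""

    name: str
    model: ModelSpec
    conditions: List[Condition]
    schedule: Optional[TitrationSchedule] = None
    anchors: Dict[str, float] = field(default_factory=dict)
    notes: str = ""

    def predict(self):
        return predict_envelope(self.model, self.conditions)


def _grid(lo: float, hi: float, step: float) -> List[float]:
    n = int(round((hi - lo) / step))
    return [round(lo + k * step, 10) for k in range(n + 1)]


def _simple_conditions(totals: Dict[str, float], ph_values: Sequence[float],
                       geometry: GeometryContext) -> List[Condition]:
    return [
        Condition(id=f"c{k + 1:02d}", pH=ph, totals=dict(totals), geometry=geometry)
        for k, ph in enumerate(ph_values)
    ]


def _fig1_model(which: str) -> ModelSpec:
    if which == "eq6":
        gamma, rxn = 2.0, ExchangeReaction(
            site="Sa", n_soh=1, consumed={"H": 1, "L": 0.5},
            product="SaOH2L0.5", occupancy=1, pK=-7.51)
    elif which == "eq7":
        gamma, rxn = 2.0, _l_reaction("Sa", -18.72)
    else:  # eq8: SOH + 2H+ + L2- <=> SOH2LH on a 1.0 umol/m^2 site
        gamma, rxn = 1.0, ExchangeReaction(
            site="Sa", n_soh=1, consumed={"H": 2, "L": 1},
            product="SaOH2LH", occupancy=1, pK=-15.02)
    return ModelSpec(
        sites=[SurfaceSite(name="Sa", gamma_max=gamma)],
        components=COMPONENTS,
        surface_reactions=[rxn],
        aqueous_reactions=[],  # no aqueous protonation in this simulation
        geometry=SIMULATION_GEOMETRY,
    )


def _fig2_model(with_cl: bool) -> ModelSpec:
    reactions = [_l_reaction("Sa", -18.7)]
    if with_cl:
        reactions.append(_cl_reaction("Sa", -8.0))
    return ModelSpec(
        sites=[SurfaceSite(name="Sa", gamma_max=2.0)],
        components=COMPONENTS,
        surface_reactions=reactions,
        aqueous_reactions=[],
        geometry=SIMULATION_GEOMETRY,
    )


def _fig2_variable_cl_total(ph: float) -> float:
    """Total Cl (mol/L): 1.27 mM above pH 3.18, rising along the acid
    additions to 4.54 mM at pH 2.33 (linear in pH between the two printed
    anchors and extrapolated below)."""
    if ph >= 3.18:
        return 1.27e-3
    return 1.27e-3 + (4.54e-3 - 1.27e-3) * (3.18 - ph) / (3.18 - 2.33)


def _table1_model() -> ModelSpec:
    sites = [SurfaceSite(name="Sa", gamma_max=2.2),
             SurfaceSite(name="Sb", gamma_max=1.3),
             SurfaceSite(name="Sc", gamma_max=0.5),
             SurfaceSite(name="Sd", gamma_max=0.4)]
    reactions = [
        _cl_reaction("Sa", -5.6), _na_reaction("Sa", 8.8, fixed=True),
        _cl_reaction("Sb", -6.6), _na_reaction("Sb", 8.8, fixed=True),
        _cl_reaction("Sc", -8.7), _na_reaction("Sc", 6.8),
        _cl_reaction("Sd", -10.5), _na_reaction("Sd", 2.8),
    ]
    return ModelSpec(sites=sites, components=COMPONENTS,
                     surface_reactions=reactions, aqueous_reactions=[],
                     geometry=GOETHITE_GEOMETRY)


def _table2_model() -> ModelSpec:
    sites = [SurfaceSite(name="Sa", gamma_max=2.2),
             SurfaceSite(name="Sb", gamma_max=1.3),
             SurfaceSite(name="Sc", gamma_max=0.5),
             SurfaceSite(name="Sd", gamma_max=0.4)]
    reactions = [
        _cl_reaction("Sa", -6.6), _na_reaction("Sa", 8.8, fixed=True),
        _l_reaction("Sa", -17.4),
        _cl_reaction("Sb", -6.6), _na_reaction("Sb", 8.8, fixed=True),
        _l_reaction("Sb", -20.8, tie="L_bcd"),
        _cl_reaction("Sc", -8.7), _na_reaction("Sc", 8.8),
        _l_reaction("Sc", -20.8, tie="L_bcd"),
        _cl_reaction("Sd", -10.5), _na_reaction("Sd", 5.4),
        _l_reaction("Sd", -20.8, tie="L_bcd"),
    ]
    return ModelSpec(sites=sites, components=COMPONENTS,
                     surface_reactions=reactions,
                     aqueous_reactions=list(PHTHALATE_AQUEOUS),
                     geometry=GOETHITE_GEOMETRY)


#: default synthetic pH grid: 28 points spanning the experimental range
DEFAULT_PH_GRID = [round(x, 2) for x in np.linspace(2.3, 10.4, 28)]


def default_titration_schedule(
    ph_values: Sequence[float],
    zpt: float = 6.41,
    phthalate_mM: float = 0.0,
    geometry: GeometryContext = GOETHITE_GEOMETRY,
    total_sites_gamma: float = 4.4,
) -> TitrationSchedule:
    """A plausible HCl/NaOH dosing schedule reaching the requested pH values.

    The dose emulates what a batch titration consumes: the free acid/base at
    the target pH relative to the zero point of titration (ZPT), plus the
    protons taken up or released by the surface (total site pool, sigmoid in
    pH), plus — when phthalate is present — the acid/base absorbed by the
    aqueous phthalate buffer.  It reproduces the observed magnitudes (e.g.
    total Cl- of a few mM at pH 2.3 over a 0.15 mM NaCl background).
    """
    area = geometry.area_per_liter
    cap = total_sites_gamma * area * 1e-6  # mol/L of total sites
    l_tot = phthalate_mM * 1e-3

    def protons_bound(ph: float) -> float:
        # surface proton load (mol/L), saturating at low pH
        return cap / (1.0 + 10.0 ** (ph - 4.5))

    def buffer_protons(ph: float) -> float:
        if l_tot == 0.0:
            return 0.0
        f = diprotic_fractions(ph, *PHTHALATE_PKA)
        return l_tot * (2.0 * f["H2A"] + f["HA"])

    vol_l = 0.035
    doses = []
    for ph in ph_values:
        acid = base = 0.0
        free_acid = 10.0 ** (-ph) - 10.0 ** (-zpt)
        surf = protons_bound(ph) - protons_bound(zpt)
        buff = buffer_protons(ph) - buffer_protons(zpt)
        demand = free_acid + surf + buff  # mol/L of strong acid needed
        if demand >= 0:
            acid = demand * vol_l * 1e3  # mmol
        else:
            base = -demand * vol_l * 1e3
        doses.append(TitrantDose(acid_mmol=acid, base_mmol=base))
    background = {"Na": 0.15e-3, "Cl": 0.15e-3}
    fixed = {"L": l_tot} if l_tot > 0 else {}
    return TitrationSchedule(
        background=background, fixed_additions=fixed,
        acid=Titrant(conjugate="Cl", molarity=0.020),
        base=Titrant(conjugate="Na", molarity=0.024),
        final_volume_ml=35.0, doses=doses,
    )


SCENARIO_NAMES = [
    "fig1_eq6", "fig1_eq7", "fig1_eq8",
    "fig2_noCl", "fig2_fixedCl", "fig2_variableCl",
    "table1_goethite", "table2_goethite_phthalate",
]


def load_scenario(name: str) -> Scenario:
    """Return a fully parameterized, runnable scenario by name."""
    geometry = SIMULATION_GEOMETRY
    if name.startswith("fig1_"):
        which = name.split("_")[1]
        if which not in ("eq6", "eq7", "eq8"):
            raise KeyError(name)
        model = _fig1_model(which)
        conds = _simple_conditions({"L": 1e-3}, _grid(2.0, 11.0, 0.25), geometry)
        pk = {"eq6": -7.51, "eq7": -18.72, "eq8": -15.02}[which]
        return Scenario(
            name=name, model=model, conditions=conds,
            anchors={"pK": pk, "datum_pH": 6.0, "datum_gamma": 0.5},
            notes="single-reaction formulation pinned through (pH 6, 0.5 umol/m^2); "
                  "total phthalate 1.0 mM, no aqueous protonation",
        )
    if name == "fig2_noCl":
        model = _fig2_model(with_cl=False)
        conds = _simple_conditions({"L": 1e-3}, _grid(2.0, 11.0, 0.25), geometry)
        return Scenario(name=name, model=model, conditions=conds,
                        anchors={"plateau_gamma_L": 1.0},
                        notes="bidentate phthalate only; plateau at capacity/2")
    if name == "fig2_fixedCl":
        model = _fig2_model(with_cl=True)
        conds = _simple_conditions({"L": 1e-3, "Cl": 4.54e-3},
                                   _grid(2.0, 11.0, 0.25), geometry)
        return Scenario(name=name, model=model, conditions=conds,
                        anchors={"plateau_gamma_L": 0.722, "plateau_gamma_Cl": 0.556},
                        notes="constant 4.54 mM Cl- competitor lowers the phthalate "
                              "plateau without moving the edge")
    if name == "fig2_variableCl":
        model = _fig2_model(with_cl=True)
        ph_values = _grid(2.0, 11.0, 0.25)
        conds = [
            Condition(id=f"c{k + 1:02d}", pH=ph,
                      totals={"L": 1e-3, "Cl": _fig2_variable_cl_total(ph)},
                      geometry=geometry)
            for k, ph in enumerate(ph_values)
        ]
        return Scenario(name=name, model=model, conditions=conds,
                        anchors={"cl_total_above_318_mM": 1.27,
                                 "cl_total_at_233_mM": 4.54},
                        notes="Cl- total rises below pH 3.18 with the HCl additions")
    if name == "table1_goethite":
        model = _table1_model()
        schedule = default_titration_schedule(DEFAULT_PH_GRID, zpt=6.41)
        conds = build_conditions(schedule, list(DEFAULT_PH_GRID), GOETHITE_GEOMETRY)
        return Scenario(name=name, model=model, conditions=conds, schedule=schedule,
                        anchors={"total_gamma_max": 4.4},
                        notes="four-site Cl-/Na+/H+ exchange model")
    if name == "table2_goethite_phthalate":
        model = _table2_model()
        schedule = default_titration_schedule(DEFAULT_PH_GRID, zpt=3.18,
                                              phthalate_mM=1.0)
        conds = build_conditions(schedule, list(DEFAULT_PH_GRID), GOETHITE_GEOMETRY)
        return Scenario(name=name, model=model, conditions=conds, schedule=schedule,
                        anchors={"total_gamma_max": 4.4},
                        notes="four-site competitive model with phthalate; sites "
                              "Sb/Sc/Sd share one phthalate pK (tie group L_bcd)")
    raise KeyError(f"unknown scenario {name!r}; known: {', '.join(SCENARIO_NAMES)}")


def generate_synthetic_envelope(
    model: ModelSpec,
    schedule: TitrationSchedule,
    ph_grid: Sequence[float],
    noise: NoiseModel,
    geometry: Optional[GeometryContext] = None,
    ions: Optional[List[str]] = None,
) -> EnvelopeDataset:
    """Forward-predict an envelope and add Gaussian measurement noise.

    With sigma = 0 the observations equal the predictions exactly; a fixed
    seed reproduces the dataset bit-for-bit.  The generating pK values are
    recorded in the dataset metadata for parameter-recovery studies.
    """
    if min(ph_grid) < 2.0 or max(ph_grid) > 11.0:
        raise ValueError("synthetic pH grid must lie within [2, 11]")
    geometry = geometry or model.geometry or GOETHITE_GEOMETRY
    conditions = build_conditions(schedule, list(ph_grid), geometry)
    envelope = predict_envelope(model, conditions)
    if ions is None:
        ions = ["H"] + [c.name for c in model.components if c.name != "H"]
        ions = [i for i in ions if f"gamma_{i}" in envelope.columns]
    rng = np.random.default_rng(noise.seed)
    observations = {}
    for _, row in envelope.iterrows():
        for ion in ions:
            sigma = noise.sigma_for(ion)
            eps = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            observations[(row["condition_id"], ion)] = float(row[f"gamma_{ion}"] + eps)
    return EnvelopeDataset(
        conditions=conditions,
        observations=observations,
        metadata={"true_pks": {r.product: r.pK for r in model.surface_reactions},
                  "noise_sigma": noise.sigma, "seed": noise.seed},
    )
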