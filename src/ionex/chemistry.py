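"""Domain types for strict charge-neutral ion-exchange models.

A model is a set of surface sites on a mineral (e.g. the ≡FeOH groups of
goethite), a set of surface exchange reactions that consume bare SOH groups
plus aqueous ions and produce *charge-neutral* surface complexes, and a set
of aqueous formation reactions (acid/base protonation, ion pairs).

The "strict" part of the theory is that no charged surface species exist:
every adsorption of an ion is paired with coadsorption of counter-charge or
release of like charge, so no surface-potential or diffuse-layer terms are
needed.  Equilibrium constants are on a concentration (molar) basis.

Proton (``"H"``) and hydroxide (``"OH"``) are built-in components whose free
concentrations are fixed by the pH of each condition (``[OH] = Kw/[H]``);
they never appear in a mass balance.
"""

from __future__ import annotations

import json
import math
from typing import Dict, List, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "PROTON",
    "HYDROXIDE",
    "R_GAS_KJ",
    "AqueousComponent",
    "AqueousReaction",
    "SurfaceSite",
    "ExchangeReaction",
    "GeometryContext",
    "ModelSpec",
    "site_capacity_molar",
    "gamma_max_from_capacity",
    "gibbs_free_energy",
    "formulation_shift",
    "model_to_yaml",
    "model_from_yaml",
    "model_to_json",
    "model_from_json",
]

PROTON = "H"
HYDROXIDE = "OH"

#: universal gas constant, kJ mol^-1 K^-1
R_GAS_KJ = 8.31446261815324e-3

SCHEMA_VERSION = 1

# charges of the built-in pH-controlled components
_BUILTIN_CHARGE = {PROTON: 1, HYDROXIDE: -1}


class AqueousComponent(BaseModel):
    """A basis species of the aqueous phase (e.g. Na+, Cl-, phthalate L2-)."""

    name: str
    charge: int


class AqueousReaction(BaseModel):
    """Formation of an aqueous complex from components.

    ``logk`` is the log10 formation constant on a concentration basis, for
    the reaction  sum(stoichiometry[c] * c) -> product.  H and OH may appear
    in the stoichiometry; their concentrations are fixed by pH.
    """

    product: str
    stoichiometry: Dict[str, float]
    logk: float
    charge: Optional[int] = None

    @field_validator("stoichiometry")
    @classmethod
    def _nonempty(cls, v: Dict[str, float]) -> Dict[str, float]:
        if not v:
            raise ValueError("stoichiometry must be nonempty")
        return v


class SurfaceSite(BaseModel):
    """One class of surface hydroxyl sites with a fixed total density."""

    name: str
    gamma_max: float = Field(gt=0, description="site density, umol m^-2")


class ExchangeReaction(BaseModel):
    """A charge-neutral surface exchange reaction.

    As written the reaction is::

        n_soh SOH + sum(consumed[c] * c)  <=>  product_coeff * product

    ``consumed`` holds signed coefficients of aqueous components per reaction
    as written (negative = released, e.g. the proton released by Na+/H+
    exchange).  ``occupancy`` is the number of SOH sites one unit of the
    product *species* keeps occupied; for the usual ``product_coeff == 1``
    form it equals ``n_soh``.  Fractional coefficients (e.g. a half-reaction
    written per half mole of a bidentate complex) are exact binary fractions.

    ``pK = -log10 K`` with K the concentration-basis equilibrium constant of
    the reaction as written.
    """

    site: str
    n_soh: float = Field(gt=0)
    consumed: Dict[str, float]
    product: str
    occupancy: int = Field(ge=1)
    pK: float
    product_coeff: float = Field(default=1.0, gt=0)
    tie_group: Optional[str] = None
    fixed: bool = False

    @model_validator(mode="after")
    def _check_occupancy(self) -> "ExchangeReaction":
        if not math.isfinite(self.pK):
            raise ValueError("pK must be finite")
        if abs(self.occupancy * self.product_coeff - self.n_soh) > 1e-12:
            raise ValueError(
                "occupancy * product_coeff must equal n_soh "
                f"(got {self.occupancy} * {self.product_coeff} != {self.n_soh})"
            )
        return self

    def proton_coefficient(self) -> float:
        """Net protons bound per unit of product species.

        Consuming OH- counts as releasing one proton and vice versa, so the
        value is invariant under the H+/OH- reformulation of the reaction.
        """
        h = self.consumed.get(PROTON, 0.0)
        w = self.consumed.get(HYDROXIDE, 0.0)
        return (h - w) / self.product_coeff

    def content(self, component: str) -> float:
        """Moles of an aqueous component bound per unit of product species."""
        return self.consumed.get(component, 0.0) / self.product_coeff


class GeometryContext(BaseModel):
    """Solid loading of a batch: specific surface area and solids concentration."""

    surface_area: float = Field(gt=0, description="m^2 g^-1")
    solids_conc: float = Field(gt=0, description="g L^-1")

    @property
    def area_per_liter(self) -> float:
        """Total surface area per liter of suspension, m^2 L^-1."""
        return self.surface_area * self.solids_conc


class ModelSpec(BaseModel):
    """Complete chemistry of a strict ion-exchange model."""

    sites: List[SurfaceSite]
    components: List[AqueousComponent]
    surface_reactions: List[ExchangeReaction]
    aqueous_reactions: List[AqueousReaction] = Field(default_factory=list)
    temperature: float = Field(default=293.15, gt=0, description="K")
    pkw: float = Field(default=14.0, description="-log10 of the water ion product")
    geometry: Optional[GeometryContext] = None

    @model_validator(mode="after")
    def _validate(self) -> "ModelSpec":
        site_names = [s.name for s in self.sites]
        comp_names = [c.name for c in self.components]
        if len(set(site_names)) != len(site_names):
            raise ValueError("site names must be unique")
        if len(set(comp_names)) != len(comp_names):
            raise ValueError("component names must be unique")
        charges = dict(_BUILTIN_CHARGE)
        for c in self.components:
            if c.name in _BUILTIN_CHARGE and c.charge != _BUILTIN_CHARGE[c.name]:
                raise ValueError(f"component {c.name} must carry charge {_BUILTIN_CHARGE[c.name]}")
            charges[c.name] = c.charge
        prod_names = set()
        for rxn in self.aqueous_reactions:
            if rxn.product in prod_names:
                raise ValueError(f"duplicate aqueous product {rxn.product}")
            prod_names.add(rxn.product)
            for name in rxn.stoichiometry:
                if name not in charges:
                    raise ValueError(f"aqueous reaction {rxn.product} references unknown component {name}")
            if rxn.charge is not None:
                implied = sum(v * charges[k] for k, v in rxn.stoichiometry.items())
                if abs(implied - rxn.charge) > 1e-9:
                    raise ValueError(
                        f"aqueous product {rxn.product}: declared charge {rxn.charge} "
                        f"inconsistent with stoichiometry ({implied:g})"
                    )
        for rxn in self.surface_reactions:
            if rxn.site not in site_names:
                raise ValueError(f"surface reaction {rxn.product} references unknown site {rxn.site}")
            for name in rxn.consumed:
                if name not in charges:
                    raise ValueError(f"surface reaction {rxn.product} references unknown component {name}")
            # strict charge neutrality: bare SOH is neutral, so the net ionic
            # charge consumed per reaction must vanish for the surface complex
            # to be neutral
            net = sum(v * charges[k] for k, v in rxn.consumed.items())
            if abs(net) > 1e-9:
                raise ValueError(
                    f"surface complex {rxn.product} would carry net charge {net:g}; "
                    "strict ion-exchange models admit only neutral surface species"
                )
        return self

    def charge_of(self, component: str) -> int:
        for c in self.components:
            if c.name == component:
                return c.charge
        if component in _BUILTIN_CHARGE:
            return _BUILTIN_CHARGE[component]
        raise KeyError(component)

    def site(self, name: str) -> SurfaceSite:
        for s in self.sites:
            if s.name == name:
                return s
        raise KeyError(name)

    def reactions_on(self, site_name: str) -> List[ExchangeReaction]:
        return [r for r in self.surface_reactions if r.site == site_name]


# ---------------------------------------------------------------------------
# unit conversions and thermodynamic helpers


def site_capacity_molar(gamma_max: float, geometry: GeometryContext) -> float:
    """Convert a site density (umol m^-2) to a volumetric capacity (mmol L^-1).

    capacity = gamma_max * surface_area * solids_conc, e.g. 2.0 umol m^-2 on
    a 100 m^2 L^-1 loading is 0.2 mmol L^-1 of sites.
    """
    if gamma_max < 0:
        raise ValueError("gamma_max must be >= 0")
    return gamma_max * geometry.area_per_liter * 1e-3


def gamma_max_from_capacity(capacity_mmol: float, geometry: GeometryContext) -> float:
    """Inverse of :func:`site_capacity_molar`: mmol L^-1 back to umol m^-2."""
    if capacity_mmol < 0:
        raise ValueError("capacity must be >= 0")
    return capacity_mmol * 1e3 / geometry.area_per_liter


def gibbs_free_energy(pK: float, temperature: float = 293.15) -> float:
    """Standard Gibbs free energy of reaction, kJ mol^-1.

    dG0 = -RT ln K = RT ln(10) * pK, so negative pK (large K) means a
    spontaneous, strongly favorable reaction.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return R_GAS_KJ * temperature * math.log(10.0) * pK


def formulation_shift(
    reaction: ExchangeReaction,
    variant: str,
    pkw: float = 14.0,
) -> ExchangeReaction:
    """Rewrite a surface reaction in a mathematically equivalent form.

    variants
    --------
    ``"hydroxide-release"``
        Swap the proton bookkeeping between H+ consumption and OH- release
        (or back).  Because [H][OH] = Kw is fixed at any pH, forward
        predictions are unchanged; the pK shifts by the swapped proton
        coefficient times pKw.  Self-inverse.
    ``"half-reaction"`` / ``"double"``
        Scale the whole reaction (stoichiometry and pK) by 1/2 or 2 while
        keeping the same product species, as in writing a bidentate complex
        per half mole.  K_full = K_half**2; predictions are identical.
    """
    if variant == "hydroxide-release":
        consumed = dict(reaction.consumed)
        h = consumed.pop(PROTON, 0.0)
        w = consumed.pop(HYDROXIDE, 0.0)
        if h != 0.0 and w == 0.0:
            consumed[HYDROXIDE] = -h
            new_pk = reaction.pK + h * pkw
        elif w != 0.0 and h == 0.0:
            consumed[PROTON] = -w
            new_pk = reaction.pK + w * pkw
        else:
            raise ValueError(
                "hydroxide-release shift needs a reaction with exactly one of "
                "H or OH in its stoichiometry"
            )
        return reaction.model_copy(update={"consumed": consumed, "pK": new_pk})
    if variant in ("half-reaction", "double"):
        f = 0.5 if variant == "half-reaction" else 2.0
        return reaction.model_copy(
            update={
                "n_soh": reaction.n_soh * f,
                "consumed": {k: v * f for k, v in reaction.consumed.items()},
                "product_coeff": reaction.product_coeff * f,
                "pK": reaction.pK * f,
            }
        )
    raise ValueError(f"unknown formulation variant {variant!r}")


# ---------------------------------------------------------------------------
# serialization


def _to_document(model: ModelSpec) -> dict:
    doc = model.model_dump(exclude_none=True)
    doc["schema_version"] = SCHEMA_VERSION
    return doc


def _from_document(doc: dict) -> ModelSpec:
    doc = dict(doc)
    version = doc.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {version}")
    return ModelSpec.model_validate(doc)


def model_to_yaml(model: ModelSpec, path=None) -> str:
    text = yaml.safe_dump(_to_document(model), sort_keys=False)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def model_from_yaml(source) -> ModelSpec:
    """Load a ModelSpec from a YAML string or file path."""
    try:
        is_path = "\n" not in str(source) and str(source).endswith((".yaml", ".yml"))
    except Exception:  # pragma: no cover
        is_path = False
    if is_path:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    return _from_document(doc)


def model_to_json(model: ModelSpec, path=None) -> str:
    text = json.dumps(_to_document(model), indent=2)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def model_from_json(source) -> ModelSpec:
    text = str(source)
    if text.endswith(".json"):
        with open(text, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    else:
        doc = json.loads(text)
    return _from_document(doc)
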