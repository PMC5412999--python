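"""Coupled surface + solution equilibrium at fixed (measured) pH.

Each batch condition is solved independently: the unknowns are the log free
concentrations of the aqueous components plus log {SOH} for each site class.
All equilibrium constants are concentration-basis; [H+] is set by the
condition's measured pH and [OH-] by pKw, so protons are never solved for.
The reported "proton adsorption" is the stoichiometric proton content of the
surface complexes (positive = uptake at low pH, negative = release), with
bare SOH as the zero reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from ._core import MassBalanceSystem, NonConvergenceError
from .chemistry import (
    HYDROXIDE,
    PROTON,
    ExchangeReaction,
    GeometryContext,
    ModelSpec,
    site_capacity_molar,
)

__all__ = [
    "Condition",
    "SolveResult",
    "SolverError",
    "solve_equilibrium",
    "predict_proton_adsorption",
    "predict_envelope",
]

LN10 = math.log(10.0)


class SolverError(RuntimeError):
    """Equilibrium solve failed; carries the offending condition if known."""

    def __init__(self, message: str, condition_id: Optional[str] = None,
                 residual_norm: float = float("nan")):
        if condition_id is not None:
            message = f"condition {condition_id}: {message}"
        super().__init__(message)
        self.condition_id = condition_id
        self.residual_norm = residual_norm


class Condition(BaseModel):
    """One batch point: measured equilibrium pH plus analytical totals (mol/L)."""

    id: str
    pH: float = Field(ge=0.0, le=14.0)
    totals: Dict[str, float]
    geometry: GeometryContext

    @property
    def area_per_liter(self) -> float:
        return self.geometry.area_per_liter

    def model_post_init(self, __context) -> None:
        for name, tot in self.totals.items():
            if tot < 0:
                raise ValueError(f"condition {self.id}: negative total for {name}")


@dataclass
class SolveResult:
    """Equilibrium state of one condition."""

    condition_id: str
    pH: float
    free: Dict[str, float]                       # mol/L
    aqueous: Dict[str, float]                    # complex species, mol/L
    soh: Dict[str, float]                        # bare SOH per site, mol/L
    surface: Dict[Tuple[str, str], float]        # (site, complex) -> mol/L
    adsorbed: Dict[str, float]                   # ion -> umol/m^2 (incl. derived H)
    residual_norm: float
    area_per_liter: float


def _assemble(model: ModelSpec, condition: Condition):
    """Build the mass-balance system for one condition.

    Returns (active components, kept aqueous rxns, kept surface rxns, system)
    or None for system when nothing is unknown.
    """
    ln_h = -condition.pH * LN10
    ln_oh = -(model.pkw - condition.pH) * LN10

    comps = [c.name for c in model.components if c.name not in (PROTON, HYDROXIDE)]
    totals = {c: condition.totals.get(c, 0.0) for c in comps}
    active = [c for c in comps if totals[c] > 0.0]
    sites = model.sites
    caps = {}
    for s in sites:
        cap = site_capacity_molar(s.gamma_max, condition.geometry) * 1e-3  # mol/L
        if cap <= 0:
            raise SolverError(f"site {s.name} has zero capacity", condition.id)
        caps[s.name] = cap

    nvar = len(active) + len(sites)
    index = {c: k for k, c in enumerate(active)}
    site_index = {s.name: len(active) + k for k, s in enumerate(sites)}

    rows: List[np.ndarray] = []
    consts: List[float] = []
    kept_aq: List = []
    kept_surf: List[ExchangeReaction] = []

    def fixed_ln(name: str, nu: float) -> Optional[float]:
        if name == PROTON:
            return nu * ln_h
        if name == HYDROXIDE:
            return nu * ln_oh
        return None

    for rxn in model.aqueous_reactions:
        coeffs = np.zeros(nvar)
        const = rxn.logk * LN10
        dead = False
        for name, nu in rxn.stoichiometry.items():
            fx = fixed_ln(name, nu)
            if fx is not None:
                const += fx
            elif name in index:
                coeffs[index[name]] = nu
            elif nu > 0:
                dead = True
            else:
                raise SolverError(
                    f"species {rxn.product} releases zero-total component {name}",
                    condition.id,
                )
        if not dead:
            rows.append(coeffs)
            consts.append(const)
            kept_aq.append(rxn)

    for rxn in model.surface_reactions:
        pc = rxn.product_coeff
        coeffs = np.zeros(nvar)
        const = -rxn.pK * LN10  # ln K' before /pc; K = 10**(-pK)
        dead = False
        for name, nu in rxn.consumed.items():
            fx = fixed_ln(name, nu)
            if fx is not None:
                const += fx
            elif name in index:
                coeffs[index[name]] = nu
            elif nu > 0:
                dead = True
            else:
                raise SolverError(
                    f"surface reaction {rxn.product} releases zero-total component {name}",
                    condition.id,
                )
        if dead:
            continue
        coeffs[site_index[rxn.site]] = rxn.n_soh
        # the species concentration is the pc-th root of the mass-action
        # product, so every exponent (and hence every content coefficient)
        # is divided by product_coeff
        rows.append(coeffs / pc)
        consts.append(const / pc)
        kept_surf.append(rxn)

    b = np.array([totals[c] for c in active] + [caps[s.name] for s in sites])
    A = np.array(rows).reshape(len(rows), nvar)
    system = MassBalanceSystem(A, np.array(consts), b)
    return active, index, site_index, kept_aq, kept_surf, system, totals, caps


def solve_equilibrium(model: ModelSpec, condition: Condition,
                      tol: float = 1e-12, max_iter: int = 200) -> SolveResult:
    """Solve the coupled surface/solution equilibrium for one condition.

    All surface mass-action laws, per-site capacity partitions and component
    mass balances hold at the returned state to the relative tolerance;
    violations raise :class:`SolverError`.
    """
    active, index, site_index, kept_aq, kept_surf, system, totals, caps = _assemble(
        model, condition
    )
    try:
        x, norm = system.solve(tol=tol, max_iter=max_iter)
    except NonConvergenceError as exc:
        raise SolverError(str(exc), condition.id, exc.residual_norm) from exc
    conc = system.species(x)
    n_aq = len(kept_aq)

    comps = [c.name for c in model.components if c.name not in (PROTON, HYDROXIDE)]
    free = {c: 0.0 for c in comps}
    free.update({c: float(np.exp(x[index[c]])) for c in active})
    free[PROTON] = 10.0 ** (-condition.pH)
    free[HYDROXIDE] = 10.0 ** (-(model.pkw - condition.pH))

    aqueous = {r.product: float(v) for r, v in zip(kept_aq, conc[:n_aq])}
    surface: Dict[Tuple[str, str], float] = {}
    for r, v in zip(kept_surf, conc[n_aq:]):
        surface[(r.site, r.product)] = surface.get((r.site, r.product), 0.0) + float(v)
    soh = {s.name: float(np.exp(x[site_index[s.name]])) for s in model.sites}

    to_gamma = 1e6 / condition.area_per_liter  # mol/L -> umol/m^2
    adsorbed = {}
    for c in comps:
        total_bound = sum(
            r.content(c) * conc[n_aq + i] for i, r in enumerate(kept_surf)
        )
        adsorbed[c] = float(total_bound) * to_gamma

    result = SolveResult(
        condition_id=condition.id,
        pH=condition.pH,
        free=free,
        aqueous=aqueous,
        soh=soh,
        surface=surface,
        adsorbed=adsorbed,
        residual_norm=norm,
        area_per_liter=condition.area_per_liter,
    )
    result.adsorbed[PROTON] = predict_proton_adsorption(result, model)
    _check_balances(model, condition, result, kept_surf, conc[n_aq:], totals, caps)
    return result


def _check_balances(model, condition, result, kept_surf, surf_conc, totals, caps):
    """Assert site conservation and component mass balance at the solution."""
    for s in model.sites:
        occupied = sum(
            r.occupancy * v for r, v in zip(kept_surf, surf_conc) if r.site == s.name
        )
        cap = caps[s.name]
        if abs(result.soh[s.name] + occupied - cap) > 1e-9 * cap:
            raise SolverError(f"site balance violated on {s.name}", condition.id,
                              result.residual_norm)
    for c, tot in totals.items():
        if tot <= 0:
            continue
        in_aq = sum(
            r.stoichiometry.get(c, 0.0) * result.aqueous.get(r.product, 0.0)
            for r in model.aqueous_reactions
        )
        on_surf = sum(r.content(c) * v for r, v in zip(kept_surf, surf_conc))
        if abs(result.free[c] + in_aq + on_surf - tot) > 1e-9 * tot:
            raise SolverError(f"mass balance violated for {c}", condition.id,
                              result.residual_norm)


def predict_proton_adsorption(result: SolveResult, model: ModelSpec) -> float:
    """Net proton content of the surface, umol/m^2, bare SOH as reference.

    Each complex contributes its per-unit proton coefficient (consumed H+,
    or minus released H+ as in Na+/H+ exchange; consumed OH- counts as -1 H+)
    times its concentration.  Positive = proton uptake.
    """
    by_product = {(r.site, r.product): r.proton_coefficient()
                  for r in model.surface_reactions}
    total = 0.0
    for key, conc in result.surface.items():
        total += by_product.get(key, 0.0) * conc
    return total * 1e6 / result.area_per_liter


def predict_envelope(model: ModelSpec, conditions: Sequence[Condition]) -> pd.DataFrame:
    """Predict the adsorption envelope: one solved row per condition.

    Returns a DataFrame ordered by pH with columns ``condition_id``, ``pH``,
    ``gamma_H`` and ``gamma_<ion>`` (umol/m^2) for every aqueous component,
    plus ``free_<ion>`` (mol/L).
    """
    if not conditions:
        raise ValueError("conditions must be nonempty")
    comps = [c.name for c in model.components if c.name not in (PROTON, HYDROXIDE)]
    records = []
    for cond in conditions:
        res = solve_equilibrium(model, cond)
        row = {"condition_id": cond.id, "pH": cond.pH,
               "gamma_H": res.adsorbed[PROTON]}
        for c in comps:
            row[f"gamma_{c}"] = res.adsorbed[c]
        for c in comps:
            row[f"free_{c}"] = res.free[c]
        records.append(row)
    frame = pd.DataFrame.from_records(records)
    return frame.sort_values("pH", kind="stable").reset_index(drop=True)
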