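"""pK estimation against adsorption-envelope data.

Two entry points:

* :func:`solve_single_point_pK` — the closed-form (or 1-D root) solve that
  pins a single-reaction model through one (pH, gamma) datum, as used to
  compare alternative reaction formulations on an equal footing.
* :func:`fit_pks` — staged least squares: each stage frees a small set of
  pKs (tie groups move as one parameter) against a pH window and ion subset,
  holding everything else, mirroring how multi-site envelope models are
  built up segment by segment from the features they control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import optimize

from .chemistry import HYDROXIDE, PROTON, ExchangeReaction, ModelSpec
from .conditions import EnvelopeDataset
from .solver import predict_envelope

__all__ = [
    "FitStage",
    "FitPlan",
    "FitResult",
    "FitError",
    "solve_single_point_pK",
    "fit_pks",
    "r_squared",
]

DEFAULT_BOUNDS = (-30.0, 15.0)


class FitError(RuntimeError):
    pass


class FitStage(BaseModel):
    """One optimization stage: which parameters move, against which data."""

    free: List[str] = Field(min_length=1, description="reaction products or tie groups")
    window: Tuple[float, float] = (0.0, 14.0)
    ions: Optional[List[str]] = None  # default: every observed ion

    def in_window(self, ph: float) -> bool:
        lo, hi = self.window
        return lo <= ph <= hi


class FitPlan(BaseModel):
    stages: List[FitStage]
    bounds: Dict[str, Tuple[float, float]] = Field(default_factory=dict)

    def bounds_for(self, name: str) -> Tuple[float, float]:
        return self.bounds.get(name, DEFAULT_BOUNDS)


@dataclass
class FitResult:
    pks: Dict[str, float]                 # reaction product -> fitted pK
    r2: Dict[str, float]                  # ion -> R^2 over the full dataset
    stages: List[Dict[str, object]]       # per-stage diagnostics
    residuals: pd.DataFrame
    model: ModelSpec


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """1 - SSE/SStot with SStot about the observed mean."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need equal-length sequences of at least two points")
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    if sstot == 0.0:
        raise ValueError("R^2 undefined: observed values are all identical")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sstot


def solve_single_point_pK(
    reaction: ExchangeReaction,
    datum: Tuple[float, float],
    total_l: float,
    capacity_mmol: float,
    area_per_liter: float = 100.0,
    pkw: float = 14.0,
) -> float:
    """pK that makes a one-reaction model pass through one envelope datum.

    ``datum`` is (pH, gamma_target in umol/m^2) for the single adsorbing
    component of the reaction; ``total_l`` is that component's total (mol/L)
    and ``capacity_mmol`` the site capacity (mmol/L).  No aqueous complexation
    is assumed, so the mass-action law inverts in closed form.
    """
    ph, gamma = datum
    cap = capacity_mmol * 1e-3
    adsorbing = [c for c in reaction.consumed
                 if c not in (PROTON, HYDROXIDE) and reaction.consumed[c] > 0]
    if len(adsorbing) != 1:
        raise FitError("single-point solve needs exactly one adsorbing component")
    comp = adsorbing[0]
    content = reaction.content(comp)             # mol of comp per product unit
    occupancy = reaction.occupancy

    bound = gamma * area_per_liter * 1e-6        # mol/L of comp on the surface
    product = bound / content                    # mol/L of product species
    sat_sites = cap / occupancy * content * 1e6 / area_per_liter
    if bound >= total_l or product * occupancy >= cap:
        limit = min(sat_sites, total_l * 1e6 / area_per_liter)
        raise FitError(
            f"datum gamma={gamma} umol/m^2 infeasible: saturation limit "
            f"{limit:.6g} umol/m^2"
        )
    free_comp = total_l - bound
    soh = cap - occupancy * product

    ln_h = -ph * math.log(10.0)
    ln_oh = -(pkw - ph) * math.log(10.0)
    ln_k = reaction.product_coeff * math.log(product) - reaction.n_soh * math.log(soh)
    for name, nu in reaction.consumed.items():
        if name == PROTON:
            ln_k -= nu * ln_h
        elif name == HYDROXIDE:
            ln_k -= nu * ln_oh
        else:
            ln_k -= nu * math.log(free_comp)
    return -ln_k / math.log(10.0)


def _parameter_map(model: ModelSpec, names: Sequence[str]) -> Dict[str, List[int]]:
    """Resolve parameter names (product or tie group) to reaction indices."""
    out: Dict[str, List[int]] = {}
    for name in names:
        idx = [
            i for i, r in enumerate(model.surface_reactions)
            if r.product == name or r.tie_group == name
        ]
        if not idx:
            raise FitError(f"no reaction or tie group named {name!r}")
        for i in idx:
            if model.surface_reactions[i].fixed:
                raise FitError(f"reaction {name!r} is marked fixed and cannot be freed")
        out[name] = idx
    return out


def _with_pks(model: ModelSpec, updates: Dict[int, float]) -> ModelSpec:
    reactions = [
        r.model_copy(update={"pK": updates[i]}) if i in updates else r
        for i, r in enumerate(model.surface_reactions)
    ]
    return model.model_copy(update={"surface_reactions": reactions})


def _stage_points(dataset: EnvelopeDataset, stage: FitStage):
    ions = stage.ions or dataset.observed_ions()
    conds = [c for c in dataset.conditions if stage.in_window(c.pH)]
    points = [
        (c, ion, dataset.observations[(c.id, ion)])
        for c in conds
        for ion in ions
        if (c.id, ion) in dataset.observations
    ]
    return conds, points


def fit_pks(
    model: ModelSpec,
    dataset: EnvelopeDataset,
    plan: FitPlan,
    weights: Optional[Dict[str, float]] = None,
) -> FitResult:
    """Staged least-squares pK optimization.

    Per stage, minimizes the unweighted (or per-ion weighted) sum of squared
    gamma residuals over the stage's pH window and ion subset with every
    other pK held, starting from the incoming values (deterministic,
    bounded derivative-free local search).  Reports per-ion R^2 over the
    full dataset for the final model.
    """
    weights = weights or {}
    current = model
    diagnostics: List[Dict[str, object]] = []

    for stage_no, stage in enumerate(plan.stages):
        pmap = _parameter_map(current, stage.free)
        conds, points = _stage_points(dataset, stage)
        if not points:
            raise FitError(f"stage {stage_no}: no observations in window {stage.window}")
        names = list(pmap)
        x0 = np.array([current.surface_reactions[pmap[n][0]].pK for n in names])
        bounds = [plan.bounds_for(n) for n in names]
        for n, (lo, hi), v in zip(names, bounds, x0):
            if not lo <= v <= hi:
                raise FitError(f"stage {stage_no}: start pK for {n!r} outside bounds")

        def objective(theta: np.ndarray) -> float:
            updates = {i: t for n, t in zip(names, theta) for i in pmap[n]}
            trial = _with_pks(current, updates)
            env = predict_envelope(trial, conds).set_index("condition_id")
            sse = 0.0
            for cond, ion, obs in points:
                pred = env.at[cond.id, f"gamma_{ion}"]
                sse += weights.get(ion, 1.0) * (obs - pred) ** 2
            return sse

        if len(names) == 1 and bounds[0][0] > -math.inf:
            res = optimize.minimize_scalar(
                lambda t: objective(np.array([t])),
                bounds=bounds[0], method="bounded",
                options={"xatol": 1e-10},
            )
            theta, fval, ok, msg = np.array([res.x]), res.fun, res.success, res.message
        else:
            res = optimize.minimize(
                objective, x0, method="Powell", bounds=bounds,
                options={"xtol": 1e-10, "ftol": 1e-14, "maxiter": 2000},
            )
            theta, fval, ok, msg = res.x, res.fun, res.success, str(res.message)
        if not ok:
            raise FitError(f"stage {stage_no} did not converge: {msg}")
        # a stage must never leave the objective worse than it found it
        f0 = objective(x0)
        if fval > f0 + 1e-12:
            theta, fval = x0, f0
        updates = {i: t for n, t in zip(names, theta) for i in pmap[n]}
        current = _with_pks(current, updates)
        diagnostics.append(
            {"stage": stage_no, "free": names,
             "pks": {n: float(t) for n, t in zip(names, theta)},
             "sse": float(fval), "n_points": len(points), "window": stage.window}
        )

    env = predict_envelope(current, dataset.conditions).set_index("condition_id")
    rows = []
    for (cid, ion), obs in sorted(dataset.observations.items()):
        pred = float(env.at[cid, f"gamma_{ion}"])
        rows.append({"condition_id": cid, "pH": float(env.at[cid, "pH"]),
                     "ion": ion, "observed": obs, "predicted": pred,
                     "residual": obs - pred})
    residuals = pd.DataFrame(rows)
    r2 = {}
    for ion in dataset.observed_ions():
        sub = residuals[residuals["ion"] == ion]
        if len(sub) >= 2 and sub["observed"].nunique() > 1:
            r2[ion] = r_squared(sub["observed"], sub["predicted"])
    pks = {r.product: r.pK for r in current.surface_reactions}
    return FitResult(pks=pks, r2=r2, stages=diagnostics, residuals=residuals,
                     model=current)
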