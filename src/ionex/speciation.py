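"""Aqueous-phase equilibrium speciation at fixed pH.

Covers diprotic acid protonation (e.g. phthalate H2L/HL-/L2-), ion pairs
(e.g. NaL-) and hydroxide, solved by Newton iteration on the log free
component concentrations so that arbitrary species sets are handled
uniformly, even where a closed form exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from ._core import MassBalanceSystem, NonConvergenceError
from .chemistry import HYDROXIDE, PROTON, AqueousReaction

__all__ = ["SpeciationResult", "speciate", "diprotic_fractions"]

LN10 = math.log(10.0)


@dataclass
class SpeciationResult:
    """Free and complexed concentrations, plus per-component species fractions.

    ``fractions[component]`` maps each species holding that component
    (including the free ion, keyed by the component's own name) to its share
    of the component's total; shares sum to 1.
    """

    free: Dict[str, float]
    species: Dict[str, float]
    fractions: Dict[str, Dict[str, float]] = field(default_factory=dict)
    residual_norm: float = 0.0


def _component_names(totals: Dict[str, float]) -> List[str]:
    return [c for c in totals if c not in (PROTON, HYDROXIDE)]


def speciate(
    totals: Dict[str, float],
    pH: float,
    reactions: Sequence[AqueousReaction],
    pkw: float = 14.0,
    tol: float = 1e-12,
) -> SpeciationResult:
    """Solve mass action + mass balance for the aqueous phase at fixed pH.

    ``totals`` are analytical component concentrations in mol/L.  [H+] is
    10**(-pH), never a solved unknown; [OH-] follows from pkw.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} outside [0, 14]")
    for name, tot in totals.items():
        if tot < 0:
            raise ValueError(f"negative total for {name}")
    ln_h = -pH * LN10
    ln_oh = -(pkw - pH) * LN10

    comps = _component_names(totals)
    active = [c for c in comps if totals[c] > 0.0]
    index = {c: k for k, c in enumerate(active)}

    rows, consts, kept = [], [], []
    for rxn in reactions:
        coeffs = np.zeros(len(active))
        const = rxn.logk * LN10
        dead = False
        for name, nu in rxn.stoichiometry.items():
            if name == PROTON:
                const += nu * ln_h
            elif name == HYDROXIDE:
                const += nu * ln_oh
            elif name in index:
                coeffs[index[name]] = nu
            elif nu > 0:
                dead = True  # requires a component whose total is zero
            else:
                raise ValueError(
                    f"species {rxn.product} releases component {name} with zero total"
                )
        if not dead:
            rows.append(coeffs)
            consts.append(const)
            kept.append(rxn)

    if active:
        system = MassBalanceSystem(
            np.array(rows).reshape(len(rows), len(active)),
            np.array(consts),
            np.array([totals[c] for c in active]),
        )
        x, norm = system.solve(tol=tol)
        conc = system.species(x)
    else:
        x = np.zeros(0)
        norm = 0.0
        conc = np.zeros(len(kept))  # nothing can form

    free = {c: 0.0 for c in comps}
    free.update({c: float(np.exp(x[index[c]])) for c in active})
    free[PROTON] = 10.0 ** (-pH)
    free[HYDROXIDE] = 10.0 ** (-(pkw - pH))

    species = {rxn.product: float(v) for rxn, v in zip(kept, conc)}

    fractions: Dict[str, Dict[str, float]] = {}
    for c in active:
        shares = {c: free[c] / totals[c]}
        for rxn, v in zip(kept, conc):
            nu = rxn.stoichiometry.get(c, 0.0)
            if nu:
                shares[rxn.product] = nu * float(v) / totals[c]
        fractions[c] = shares
    return SpeciationResult(free=free, species=species, fractions=fractions, residual_norm=norm)


def diprotic_fractions(pH: float, pka1: float, pka2: float) -> Dict[str, float]:
    """Closed-form alpha fractions of a diprotic acid (H2A, HA, A).

    Independent of the iterative solver; used as an oracle for it.
    """
    h = 10.0 ** (-pH)
    ka1, ka2 = 10.0 ** (-pka1), 10.0 ** (-pka2)
    denom = h * h + h * ka1 + ka1 * ka2
    return {
        "H2A": h * h / denom,
        "HA": h * ka1 / denom,
        "A": ka1 * ka2 / denom,
    }
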