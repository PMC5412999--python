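"""Shared mass-action / mass-balance Newton solver.

Both the aqueous speciation problem and the coupled surface+solution
equilibrium reduce to the same algebraic form.  Unknowns are natural logs of
the free concentrations of the balance carriers (aqueous components and, for
the surface problem, bare SOH per site).  Every derived species is a pure
power-law of the unknowns::

    ln S_i = const_i + sum_k A[i, k] * x_k

and each balance row k requires::

    exp(x_k) + sum_i A[i, k] * S_i = b_k

The coefficient that sets a species' sensitivity to unknown k equals its
content of carrier k, which is what makes the Jacobian

    J = diag(exp(x)) + A^T diag(S) A

symmetric positive semidefinite and Newton iteration in log space extremely
robust: concentrations can never go negative and problems spanning 15+
orders of magnitude converge in a handful of steps.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

__all__ = ["MassBalanceSystem", "NonConvergenceError"]


class NonConvergenceError(RuntimeError):
    """Raised when the equilibrium iteration fails to meet tolerance."""

    def __init__(self, message: str, residual_norm: float, last_x: np.ndarray):
        super().__init__(f"{message} (residual norm {residual_norm:.3e})")
        self.residual_norm = residual_norm
        self.last_x = last_x


class MassBalanceSystem:
    """One equilibrium problem: fixed-activity species folded into ``const``.

    Parameters
    ----------
    A
        (n_species, n_unknowns) content matrix.
    const
        (n_species,) natural-log prefactors (formation constants plus the
        contribution of pH-fixed species).
    b
        (n_unknowns,) total (mass balance) for each carrier; strictly > 0.
    """

    def __init__(self, A: np.ndarray, const: np.ndarray, b: np.ndarray):
        self.A = np.asarray(A, dtype=float)
        self.const = np.asarray(const, dtype=float)
        self.b = np.asarray(b, dtype=float)
        if np.any(self.b <= 0):
            raise ValueError("all balance totals must be positive")

    def species(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.const + self.A @ x)

    def residual(self, x: np.ndarray) -> np.ndarray:
        """Scaled (relative) mass-balance residual."""
        s = self.species(x)
        g = np.exp(x) + (self.A.T @ s if len(s) else 0.0) - self.b
        return g / self.b

    def solve(
        self,
        x0: np.ndarray | None = None,
        tol: float = 1e-12,
        max_iter: int = 200,
        max_step: float = 8.0,
    ) -> tuple[np.ndarray, float]:
        """Damped Newton iteration; returns (x, residual_inf_norm)."""
        x = np.log(self.b) if x0 is None else np.asarray(x0, dtype=float).copy()
        n = len(self.b)
        g = self.residual(x)
        norm = float(np.max(np.abs(g))) if n else 0.0
        for _ in range(max_iter):
            if norm < tol:
                return x, norm
            s = self.species(x)
            J = np.diag(np.exp(x)) + self.A.T @ (s[:, None] * self.A)
            J = J / self.b[:, None]
            try:
                step = np.linalg.solve(J, -g)
            except np.linalg.LinAlgError:
                step = None
            if step is None or not np.all(np.isfinite(step)):
                return self._fallback(x, tol)
            big = np.max(np.abs(step))
            if big > max_step:
                step *= max_step / big
            # backtracking line search on the residual norm
            lam, improved = 1.0, False
            for _ in range(40):
                x_new = x + lam * step
                g_new = self.residual(x_new)
                norm_new = float(np.max(np.abs(g_new)))
                if np.isfinite(norm_new) and norm_new < norm:
                    x, g, norm, improved = x_new, g_new, norm_new, True
                    break
                lam *= 0.5
            if not improved:
                return self._fallback(x, tol)
        if norm < tol:
            return x, norm
        return self._fallback(x, tol)

    def _fallback(self, x: np.ndarray, tol: float) -> tuple[np.ndarray, float]:
        """Derivative-free rescue via scipy's hybrid Powell method."""
        sol = optimize.root(self.residual, x, method="hybr", options={"xtol": 1e-14})
        norm = float(np.max(np.abs(self.residual(sol.x))))
        if norm < max(tol, 1e-10):
            return sol.x, norm
        raise NonConvergenceError("equilibrium solve did not converge", norm, sol.x)
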