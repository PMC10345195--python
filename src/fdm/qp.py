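"""Exact active-set solver for box-constrained minimum-norm problems.

Solves
    min 1/2 ||x||^2   s.t.   A x = b,   lb <= x <= ub

by a primal active-set iteration.  Each working-set subproblem is the
minimum-norm solution of an underdetermined linear system, obtained directly
from ``numpy.linalg.lstsq``, so the solution is accurate to machine precision.
This matters downstream: demand-flux response coefficients are estimated by
finite differences of the optimum, and a first-order solver's 1e-5 residual
would dominate a 1e-6 perturbation.

The objective is strictly convex, so the optimum is unique and the iteration
terminates finitely; ties are broken by lowest variable index to keep runs
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["solve_box_qp", "QPError", "QPResult"]


class QPError(RuntimeError):
    pass


@dataclass
class QPResult:
    x: np.ndarray
    eq_multipliers: np.ndarray
    iterations: int
    max_eq_residual: float


def _min_norm_point(A: np.ndarray, b: np.ndarray, fixed: dict[int, float], n: int) -> np.ndarray:
    """Minimum-norm x with A x = b and x_j fixed for j in ``fixed``."""
    free = np.array([j for j in range(n) if j not in fixed], dtype=int)
    x = np.zeros(n)
    rhs = b.copy()
    for j, val in fixed.items():
        x[j] = val
        rhs -= A[:, j] * val
    if free.size:
        sol, *_ = np.linalg.lstsq(A[:, free], rhs, rcond=None)
        x[free] = sol
    return x


def solve_box_qp(
    A: np.ndarray,
    b: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    x0: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> QPResult:
    """Minimise 1/2||x||^2 subject to A x = b and lb <= x <= ub.

    ``x0`` must be feasible (typically a vertex returned by the stage-1 LP).
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    n = A.shape[1]
    x = np.asarray(x0, dtype=float).copy()

    if np.any(x < lb - 1e-7) or np.any(x > ub + 1e-7):
        raise QPError("starting point violates bounds")
    eq_res = np.abs(A @ x - b).max() if A.size else 0.0
    if eq_res > 1e-6 * max(1.0, np.abs(b).max(initial=1.0)):
        raise QPError(f"starting point violates equalities (residual {eq_res:.2e})")
    x = np.clip(x, lb, ub)

    # working set: variable index -> bound value it is pinned at
    scale = max(1.0, np.abs(x).max())
    working: dict[int, float] = {}
    for j in range(n):
        if np.isfinite(lb[j]) and x[j] - lb[j] <= 1e-9 * scale:
            working[j] = lb[j]
        elif np.isfinite(ub[j]) and ub[j] - x[j] <= 1e-9 * scale:
            working[j] = ub[j]

    lam = np.zeros(A.shape[0])
    for it in range(1, max_iter + 1):
        target = _min_norm_point(A, b, working, n)
        p = target - x
        step_norm = np.abs(p).max(initial=0.0)
        if step_norm <= tol * max(1.0, np.abs(x).max()):
            # stationary on the working set: check bound multipliers.
            free = [j for j in range(n) if j not in working]
            if free:
                lam, *_ = np.linalg.lstsq(A[:, free].T, x[free], rcond=None)
            else:
                lam, *_ = np.linalg.lstsq(A.T, x, rcond=None)
            # stationarity: x = A^T lam + mu with mu_j >= 0 at a lower bound
            # and mu_j <= 0 at an upper bound (else the bound can be released).
            mu = x - A.T @ lam
            worst_j, worst_v = -1, tol * max(1.0, np.abs(x).max())
            for j, val in working.items():
                if lb[j] == ub[j]:
                    continue  # genuinely fixed variable, never released
                at_lower = np.isfinite(lb[j]) and val == lb[j]
                viol = -mu[j] if at_lower else mu[j]
                if viol > worst_v:
                    worst_j, worst_v = j, viol
            if worst_j == -1:
                res = np.abs(A @ x - b).max() if A.size else 0.0
                return QPResult(x=x, eq_multipliers=lam, iterations=it, max_eq_residual=res)
            del working[worst_j]
            continue

        # longest step along p keeping free variables inside their box
        alpha = 1.0
        blocking: tuple[int, float] | None = None
        for j in range(n):
            if j in working:
                continue
            if p[j] > tol and np.isfinite(ub[j]):
                a = (ub[j] - x[j]) / p[j]
                if a < alpha - 1e-15:
                    alpha, blocking = a, (j, ub[j])
            elif p[j] < -tol and np.isfinite(lb[j]):
                a = (lb[j] - x[j]) / p[j]
                if a < alpha - 1e-15:
                    alpha, blocking = a, (j, lb[j])
        alpha = max(alpha, 0.0)
        x = x + alpha * p
        if blocking is not None and alpha < 1.0:
            j, val = blocking
            x[j] = val
            working[j] = val

    raise QPError(f"active-set iteration did not converge in {max_iter} steps")
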