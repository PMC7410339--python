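"""Thin LP / MILP layer over scipy's HiGHS interfaces.

Everything downstream talks to these two entry points, so a different
backend only needs to reimplement this module's small contract:
a sparse/dense constraint system with variable bounds and kinds, returning
``(status, solution)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, sparse


class SolverError(RuntimeError):
    """The LP/MILP backend failed in a way that is not plain infeasibility."""


@dataclass
class LPProblem:
    """min c.x  s.t.  A_eq x = b_eq, A_ub x <= b_ub, lb <= x <= ub."""

    A_eq: np.ndarray | None = None
    b_eq: np.ndarray | None = None
    A_ub: np.ndarray | None = None
    b_ub: np.ndarray | None = None
    lb: np.ndarray | None = None
    ub: np.ndarray | None = None
    c: np.ndarray | None = None


def solve_lp(lp: LPProblem) -> tuple[str, np.ndarray | None]:
    """Solve an LP; returns ('optimal'|'infeasible'|'unbounded', x)."""
    n = _n_vars(lp)
    c = lp.c if lp.c is not None else np.zeros(n)
    lb = lp.lb if lp.lb is not None else np.full(n, -np.inf)
    ub = lp.ub if lp.ub is not None else np.full(n, np.inf)
    res = optimize.linprog(
        c,
        A_ub=lp.A_ub, b_ub=lp.b_ub,
        A_eq=lp.A_eq, b_eq=lp.b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status == 0:
        return "optimal", res.x
    if res.status == 2:
        return "infeasible", None
    if res.status == 3:
        return "unbounded", None
    raise SolverError(f"linprog failed: status={res.status} message={res.message!r}")


def _n_vars(lp: LPProblem) -> int:
    for arr in (lp.c, lp.lb, lp.ub):
        if arr is not None:
            return len(arr)
    for mat in (lp.A_eq, lp.A_ub):
        if mat is not None:
            return np.shape(mat)[1]
    raise ValueError("cannot infer variable count")


def solve_milp(
    c: np.ndarray,
    A: sparse.csr_matrix,
    row_lb: np.ndarray,
    row_ub: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    integrality: np.ndarray,
    time_limit: float | None = None,
) -> tuple[str, np.ndarray | None, float | None]:
    """Solve min c.x s.t. row_lb <= A x <= row_ub, lb <= x <= ub.

    ``integrality`` is 0 (continuous) / 1 (integer) per variable.  Returns
    ``(status, x, objective)`` with status 'optimal' | 'infeasible' |
    'timeout' | 'unbounded'.
    """
    options = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = optimize.milp(
        c,
        constraints=optimize.LinearConstraint(A, row_lb, row_ub),
        bounds=optimize.Bounds(lb, ub),
        integrality=integrality,
        options=options,
    )
    if res.status == 0:
        return "optimal", res.x, float(res.fun)
    if res.status == 2:
        return "infeasible", None, None
    if res.status == 1:  # iteration/time limit
        if res.x is not None:
            return "timeout", res.x, float(res.fun)
        return "timeout", None, None
    if res.status == 3:
        return "unbounded", None, None
    raise SolverError(f"milp failed: status={res.status} message={res.message!r}")
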