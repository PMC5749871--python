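"""Thin LP/MILP backend over scipy's HiGHS interfaces.

The solver contract the rest of the package relies on: a call either returns a
provably optimal solution (MIP gap 0 for integer problems) or raises an error
carrying the solver status.  Pure LPs are routed to ``linprog`` with tightened
feasibility tolerances; problems with integer variables go to ``milp``.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

__all__ = [
    "SolverError",
    "InfeasibleProblemError",
    "UnboundedProblemError",
    "solve_linear",
    "SOLVER_IDENTITY",
]

SOLVER_IDENTITY = "scipy-HiGHS"

# LP tolerances tightened well below the 1e-9 occupancy-sum invariant.
_LP_OPTIONS = {
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-10,
}
_MIP_OPTIONS = {"mip_rel_gap": 0.0}


class SolverError(RuntimeError):
    """Solver terminated without a provably optimal solution."""

    def __init__(self, message: str, status: int | None = None):
        super().__init__(message)
        self.status = status


class InfeasibleProblemError(SolverError):
    pass


class UnboundedProblemError(SolverError):
    pass


def solve_linear(
    objective: np.ndarray,
    *,
    A_ub=None,
    b_ub=None,
    A_eq=None,
    b_eq=None,
    lb=None,
    ub=None,
    integrality=None,
    maximize: bool = True,
    context: str = "",
    time_limit: float | None = None,
) -> tuple[np.ndarray, float]:
    """Solve max (or min) ``objective . x`` and return ``(x, optimal value)``.

    ``time_limit`` (seconds) caps the solver's wall clock; expiry raises
    :class:`SolverError` — an unproven incumbent is never returned silently.
    """
    c = np.asarray(objective, dtype=float)
    n = c.size
    sign = -1.0 if maximize else 1.0
    lb = np.zeros(n) if lb is None else np.asarray(lb, dtype=float)
    ub = np.full(n, np.inf) if ub is None else np.asarray(ub, dtype=float)
    is_mip = integrality is not None and np.any(np.asarray(integrality) > 0)

    if is_mip:
        constraints = []
        if A_ub is not None and np.size(b_ub):
            constraints.append(LinearConstraint(sp.csc_array(A_ub), -np.inf, np.asarray(b_ub, dtype=float)))
        if A_eq is not None and np.size(b_eq):
            beq = np.asarray(b_eq, dtype=float)
            constraints.append(LinearConstraint(sp.csc_array(A_eq), beq, beq))
        options = dict(_MIP_OPTIONS)
        if time_limit is not None:
            options["time_limit"] = float(time_limit)

        def run_milp(opts):
            return milp(
                c=sign * c,
                constraints=constraints,
                integrality=np.asarray(integrality),
                bounds=Bounds(lb, ub),
                options=opts,
            )

        res = run_milp(options)
        if res.status == 4:
            # HiGHS presolve occasionally fails outright on valid instances;
            # a presolve-free retry resolves those cases
            res = run_milp(dict(options, presolve=False))
        status_map = {2: InfeasibleProblemError, 3: UnboundedProblemError}
    else:
        res = linprog(
            c=sign * c,
            A_ub=None if A_ub is None or not np.size(b_ub) else sp.csc_array(A_ub),
            b_ub=None if b_ub is None or not np.size(b_ub) else np.asarray(b_ub, dtype=float),
            A_eq=None if A_eq is None or not np.size(b_eq) else sp.csc_array(A_eq),
            b_eq=None if b_eq is None or not np.size(b_eq) else np.asarray(b_eq, dtype=float),
            bounds=np.column_stack([lb, ub]),
            method="highs",
            options=dict(_LP_OPTIONS, **({"time_limit": float(time_limit)} if time_limit is not None else {})),
        )
        status_map = {2: InfeasibleProblemError, 3: UnboundedProblemError}

    if res.status != 0 or res.x is None:
        exc = status_map.get(res.status, SolverError)
        where = f" while {context}" if context else ""
        raise exc(f"solver status {res.status}{where}: {res.message}", status=res.status)
    return np.asarray(res.x, dtype=float), float(sign * res.fun)
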