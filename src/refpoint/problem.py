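"""Multi-objective linear/mixed-integer problem container.

A :class:`MultiObjectiveProblem` is the common currency of the package: a set
of decision variables (continuous or integer), linear constraints, and ``p >= 2``
linear criteria, all oriented as MAXIMIZE.  Problem families (multi-objective
MDPs, spatial allocation, discrete point-selection toys) are compiled down to
this form and then scalarized and solved by :mod:`refpoint.scalarize`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["MultiObjectiveProblem", "SolutionPoint", "from_point_list"]


def _as_sparse(A, n_cols: int) -> sp.csr_array:
    if A is None:
        return sp.csr_array((0, n_cols))
    if sp.issparse(A):
        return sp.csr_array(A)
    return sp.csr_array(np.atleast_2d(np.asarray(A, dtype=float)))


@dataclass
class MultiObjectiveProblem:
    """A linear/mixed-integer program with several maximize-criteria.

    Parameters
    ----------
    criteria:
        Array of shape ``(p, n)``: coefficient row per criterion, ``p >= 2``.
    criteria_offsets:
        Optional constant term per criterion (``f_j(x) = c_j . x + off_j``).
    A_ub, b_ub:
        Inequality constraints ``A_ub @ x <= b_ub`` (sparse or dense).
    A_eq, b_eq:
        Equality constraints ``A_eq @ x == b_eq``.
    lb, ub:
        Variable bounds; defaults 0 / +inf.
    integrality:
        Per-variable flags (0 continuous, 1 integer), as for `scipy.optimize.milp`.
    names:
        Optional variable names (diagnostics and serialization only).
    sampler:
        Optional hook ``sampler(rng) -> x`` returning one feasible full decision
        vector; enables the explicit (random sampling) baseline.
    enumerator:
        Optional hook ``enumerator() -> iterable of x`` yielding every feasible
        decision of a tiny instance; enables brute-force oracles.
    decision_mask:
        Optional boolean mask marking which variables constitute the *decision*
        (as opposed to auxiliary modelling variables such as travel times).
    decision_criteria:
        Optional hook ``decision_criteria(decision) -> criteria vector``
        recomputing the exact criteria of a decision independently of any
        auxiliary variables (used to report criteria from first principles
        rather than from possibly-slack epigraph variables).
    """

    criteria: np.ndarray
    criteria_offsets: np.ndarray | None = None
    A_ub: sp.sparray | np.ndarray | None = None
    b_ub: np.ndarray | None = None
    A_eq: sp.sparray | np.ndarray | None = None
    b_eq: np.ndarray | None = None
    lb: np.ndarray | None = None
    ub: np.ndarray | None = None
    integrality: np.ndarray | None = None
    names: Sequence[str] | None = None
    sampler: Callable[[np.random.Generator], np.ndarray] | None = None
    enumerator: Callable[[], Iterable[np.ndarray]] | None = None
    decision_mask: np.ndarray | None = None
    decision_criteria: Callable[[np.ndarray], np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.criteria = np.atleast_2d(np.asarray(self.criteria, dtype=float))
        p, n = self.criteria.shape
        if p < 2:
            raise ValueError(f"a multi-objective problem needs p >= 2 criteria, got p={p}")
        if self.criteria_offsets is None:
            self.criteria_offsets = np.zeros(p)
        else:
            self.criteria_offsets = np.asarray(self.criteria_offsets, dtype=float)
            if self.criteria_offsets.shape != (p,):
                raise ValueError("criteria_offsets must have one entry per criterion")
        self.A_ub = _as_sparse(self.A_ub, n)
        self.b_ub = np.zeros(0) if self.b_ub is None else np.asarray(self.b_ub, dtype=float)
        self.A_eq = _as_sparse(self.A_eq, n)
        self.b_eq = np.zeros(0) if self.b_eq is None else np.asarray(self.b_eq, dtype=float)
        if self.A_ub.shape[0] != self.b_ub.size:
            raise ValueError("A_ub / b_ub shape mismatch")
        if self.A_eq.shape[0] != self.b_eq.size:
            raise ValueError("A_eq / b_eq shape mismatch")
        self.lb = np.zeros(n) if self.lb is None else np.asarray(self.lb, dtype=float)
        self.ub = np.full(n, np.inf) if self.ub is None else np.asarray(self.ub, dtype=float)
        if self.integrality is None:
            self.integrality = np.zeros(n)
        else:
            self.integrality = np.asarray(self.integrality)
        for arr, nm in ((self.lb, "lb"), (self.ub, "ub"), (self.integrality, "integrality")):
            if arr.shape != (n,):
                raise ValueError(f"{nm} must have one entry per variable")
        if self.decision_mask is not None:
            self.decision_mask = np.asarray(self.decision_mask, dtype=bool)

    # ------------------------------------------------------------------
    @property
    def p(self) -> int:
        """Number of criteria."""
        return self.criteria.shape[0]

    @property
    def n_variables(self) -> int:
        return self.criteria.shape[1]

    @property
    def is_mip(self) -> bool:
        return bool(np.any(self.integrality > 0))

    def criteria_values(self, x: np.ndarray) -> np.ndarray:
        """Evaluate all p criteria at a full variable vector ``x``."""
        x = np.asarray(x, dtype=float)
        return self.criteria @ x + self.criteria_offsets

    def is_feasible(self, x: np.ndarray, tol: float = 1e-7) -> bool:
        """Constraint check used by the sampling baseline and tests."""
        x = np.asarray(x, dtype=float)
        if np.any(x < self.lb - tol) or np.any(x > self.ub + tol):
            return False
        if self.b_ub.size and np.any(self.A_ub @ x > self.b_ub + tol):
            return False
        if self.b_eq.size and np.any(np.abs(self.A_eq @ x - self.b_eq) > tol):
            return False
        if np.any(np.abs(x[self.integrality > 0] - np.round(x[self.integrality > 0])) > tol):
            return False
        return True

    def exact_criteria(self, x: np.ndarray) -> np.ndarray:
        """Criteria of a solution, recomputed from the decision when possible.

        Falls back to evaluating the criteria expressions on the full variable
        vector; the ``decision_criteria`` hook takes precedence because
        epigraph-style auxiliary variables need not be tight at every solver
        optimum.
        """
        if self.decision_criteria is not None:
            return np.asarray(self.decision_criteria(self.decision_of(x)), dtype=float)
        return self.criteria_values(x)

    def decision_of(self, x: np.ndarray) -> np.ndarray:
        """Extract the decision part of a full variable vector.

        Integer variables are rounded to their nearest integer value, so a
        decision coming out of a MIP solver is exactly representable.
        """
        x = np.asarray(x, dtype=float).copy()
        ints = self.integrality > 0
        x[ints] = np.round(x[ints])
        if self.decision_mask is None:
            return x
        return x[self.decision_mask]


@dataclass
class SolutionPoint:
    """A decision together with its criteria vector and provenance.

    ``method`` is one of ``reference_point``, ``weighted_sum``,
    ``explicit_sample`` or ``projection``; ``provenance`` records the reference
    point or weight vector that produced the solution.
    """

    decision: np.ndarray
    criteria: np.ndarray
    method: str
    provenance: dict = field(default_factory=dict)
    achievement: float | None = None

    def __post_init__(self) -> None:
        self.decision = np.asarray(self.decision, dtype=float)
        self.criteria = np.asarray(self.criteria, dtype=float)

    def to_record(self) -> dict:
        rec = {
            "method": self.method,
            "criteria": [float(v) for v in self.criteria],
            "decision": [float(v) for v in self.decision],
            "achievement": None if self.achievement is None else float(self.achievement),
        }
        rec.update({k: _jsonable(v) for k, v in self.provenance.items()})
        return rec

    def to_json(self) -> str:
        return json.dumps(self.to_record())


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return [float(x) for x in v]
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def from_point_list(points: Sequence[Sequence[float]]) -> MultiObjectiveProblem:
    """Build a selection problem whose feasible criteria set is exactly `points`.

    One binary variable per candidate point, with the constraint that exactly
    one is selected; criterion ``j`` is ``sum_i z_ij y_i``.  Used for crafted
    discrete instances (the unsupported-point and weak-dominance examples) and
    as an enumeration oracle in tests.
    """
    Z = np.atleast_2d(np.asarray(points, dtype=float))
    m, p = Z.shape
    if m < 1:
        raise ValueError("need at least one point")

    def enumerator():
        for i in range(m):
            x = np.zeros(m)
            x[i] = 1.0
            yield x

    def sampler(rng: np.random.Generator) -> np.ndarray:
        x = np.zeros(m)
        x[rng.integers(m)] = 1.0
        return x

    return MultiObjectiveProblem(
        criteria=Z.T,
        A_eq=np.ones((1, m)),
        b_eq=np.array([1.0]),
        lb=np.zeros(m),
        ub=np.ones(m),
        integrality=np.ones(m),
        sampler=sampler,
        enumerator=enumerator,
        meta={"kind": "point_selection"},
    )
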