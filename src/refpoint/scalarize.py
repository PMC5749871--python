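"""Achievement scalarization and the reference-point / weighted-sum solves.

The reference point method projects a decision-maker's aspiration point
``z_bar`` (one aspired value per criterion, feasible or not) onto the Pareto
frontier by maximizing the augmented achievement function

    s(x) = min_j lambda_j (f_j(x) - z_bar_j) + rho * sum_j lambda_j (f_j(x) - z_bar_j)

where ``lambda_j = 1 / (z_max_j - z_min_j)`` normalizes criterion ranges and
``rho`` is a small positive augmentation weight ruling out weakly dominated
optima.  Maximizing s over a linear feasible set is itself an LP/MILP: introduce
a free scalar ``z`` with constraints ``z <= lambda_j (f_j(x) - z_bar_j)`` and
maximize ``z + rho * sum_j lambda_j (f_j(x) - z_bar_j)``.

For suitable ``rho`` (see :func:`default_rho`) every maximizer is an efficient
decision, and every non-dominated point is recovered by using itself as the
reference point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .problem import MultiObjectiveProblem, SolutionPoint
from .solver import solve_linear

__all__ = [
    "CriteriaBounds",
    "ScalarizationConfig",
    "DegenerateCriterionError",
    "compute_bounds",
    "default_rho",
    "achievement_value",
    "solve_reference_point",
    "solve_weighted_sum",
]


class DegenerateCriterionError(ValueError):
    """A criterion has zero range (z_max == z_min)."""


@dataclass
class CriteriaBounds:
    """Per-criterion ideal/anti-ideal values and normalization weights.

    ``lam[j] = 1 / (z_max[j] - z_min[j])`` when the range is positive.  A
    criterion with zero range carries no decision information; it gets
    ``lam = 1`` and is excluded from the min-term of the achievement function
    (tracked in ``degenerate``).
    """

    z_max: np.ndarray
    z_min: np.ndarray
    lam: np.ndarray = field(init=False)
    degenerate: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.z_max = np.asarray(self.z_max, dtype=float)
        self.z_min = np.asarray(self.z_min, dtype=float)
        if self.z_max.shape != self.z_min.shape or self.z_max.ndim != 1:
            raise ValueError("z_max / z_min must be 1-d vectors of equal length")
        if np.any(self.z_max < self.z_min):
            raise ValueError("z_max must be >= z_min componentwise")
        rng = self.z_max - self.z_min
        self.degenerate = rng <= 0
        if np.any(self.degenerate):
            warnings.warn(
                "criterion(s) %s have zero range; lambda set to 1 and excluded "
                "from the min-term" % np.flatnonzero(self.degenerate).tolist(),
                stacklevel=2,
            )
        self.lam = np.where(self.degenerate, 1.0, 1.0 / np.where(self.degenerate, 1.0, rng))

    @property
    def p(self) -> int:
        return self.z_max.size

    def scale(self, criteria: np.ndarray) -> np.ndarray:
        """Map criteria vectors to [0, 1]-normalized coordinates."""
        return (np.asarray(criteria, dtype=float) - self.z_min) * self.lam


@dataclass
class ScalarizationConfig:
    """Scalarization parameters.

    ``rho`` defaults to None, meaning "derive it from the bounds at solve time"
    (half the theoretical upper bound; on instances with degenerate criteria the
    bound is computed over the informative criteria only).  ``distinct_tol`` is
    the max-norm tolerance, in scaled criteria space, under which two points
    count as the same (used by distinct-point reporting).  ``time_limit``
    (seconds) caps each scalarized solve; an expired solve raises instead of
    returning an unproven incumbent.
    """

    rho: float | None = None
    distinct_tol: float = 1e-6
    time_limit: float | None = None

    def __post_init__(self) -> None:
        if self.rho is not None and self.rho <= 0:
            raise ValueError("rho must be strictly positive")
        if self.distinct_tol < 0:
            raise ValueError("distinct_tol must be nonnegative")

    def resolve_rho(self, bounds: CriteriaBounds) -> float:
        if self.rho is not None:
            return self.rho
        return _rho_from_bounds(bounds, allow_degenerate=True)


def compute_bounds(problem: MultiObjectiveProblem) -> CriteriaBounds:
    """Ideal and anti-ideal value of each criterion via 2p single-objective solves.

    Raises the solver's infeasibility/unboundedness errors, naming the criterion
    for unbounded cases.
    """
    p = problem.p
    z_max = np.empty(p)
    z_min = np.empty(p)
    for j in range(p):
        for maximize, store in ((True, z_max), (False, z_min)):
            _, val = solve_linear(
                problem.criteria[j],
                A_ub=problem.A_ub,
                b_ub=problem.b_ub,
                A_eq=problem.A_eq,
                b_eq=problem.b_eq,
                lb=problem.lb,
                ub=problem.ub,
                integrality=problem.integrality,
                maximize=maximize,
                context=f"{'maximizing' if maximize else 'minimizing'} criterion {j}",
            )
            store[j] = val + problem.criteria_offsets[j]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bounds = CriteriaBounds(z_max=z_max, z_min=z_min)
    if np.any(bounds.degenerate):
        warnings.warn(
            "degenerate criterion(s) %s: z_max == z_min"
            % np.flatnonzero(bounds.degenerate).tolist(),
            stacklevel=2,
        )
    return bounds


def _rho_from_bounds(bounds: CriteriaBounds, allow_degenerate: bool) -> float:
    active = ~bounds.degenerate
    if not np.any(active):
        # No criterion carries information; any small positive value works.
        return 1e-3
    if np.any(bounds.degenerate) and not allow_degenerate:
        raise DegenerateCriterionError(
            "criteria %s have zero range; apply the degenerate-criterion rule "
            "before calling default_rho" % np.flatnonzero(bounds.degenerate).tolist()
        )
    ranges = (bounds.z_max - bounds.z_min)[active]
    bound = bounds.lam[active].min() / ranges.sum()
    return 0.5 * bound  # half the theoretical bound: strict with margin


def default_rho(bounds: CriteriaBounds) -> float:
    """Half of ``min_j lambda_j / sum_j (z_max_j - z_min_j)``, the safe upper bound.

    Any value strictly below the bound guarantees (in the combinatorial
    setting) that maximizers of the achievement function are never weakly
    dominated.  Raises :class:`DegenerateCriterionError` if any range is zero.
    """
    return _rho_from_bounds(bounds, allow_degenerate=False)


def achievement_value(
    criteria: np.ndarray,
    z_bar: np.ndarray,
    bounds: CriteriaBounds,
    rho: float,
) -> float:
    """Augmented achievement of a criteria vector w.r.t. reference point z_bar.

    Negative when the reference point is not attained.  Degenerate criteria are
    excluded from the min-term but kept in the augmentation sum (with lam=1).
    """
    z = np.asarray(criteria, dtype=float)
    zb = np.asarray(z_bar, dtype=float)
    if z.shape != zb.shape or z.shape != bounds.z_max.shape:
        raise ValueError("criteria / reference point / bounds length mismatch")
    terms = bounds.lam * (z - zb)
    active = ~bounds.degenerate
    min_term = terms[active].min() if np.any(active) else 0.0
    return float(min_term + rho * terms.sum())


def _assemble_rp(problem, bounds, z_bar):
    """Augment the problem with the free scalar z of the scalarized program.

    Returns the sum-term objective (over [x, z]) plus the augmented constraint
    system; degenerate criteria are excluded from the z epigraph rows but kept
    in the sum objective with lam = 1.
    """
    lam = bounds.lam
    active = np.flatnonzero(~bounds.degenerate)
    obj_sum = np.concatenate([lam @ problem.criteria, [0.0]])
    # z - lam_j f_j(x) <= lam_j (off_j - z_bar_j)   for informative j
    Az = sp.hstack(
        [
            sp.csr_array(-(lam[active, None] * problem.criteria[active])),
            sp.csr_array(np.ones((active.size, 1))),
        ],
        format="csr",
    )
    bz = lam[active] * (problem.criteria_offsets[active] - z_bar[active])
    A_ub = sp.vstack(
        [sp.hstack([problem.A_ub, sp.csr_array((problem.A_ub.shape[0], 1))]), Az],
        format="csr",
    )
    b_ub = np.concatenate([problem.b_ub, bz])
    A_eq = sp.hstack([problem.A_eq, sp.csr_array((problem.A_eq.shape[0], 1))], format="csr")
    lb = np.concatenate([problem.lb, [-np.inf]])
    ub = np.concatenate([problem.ub, [np.inf]])
    integrality = np.concatenate([problem.integrality, [0]])
    return obj_sum, A_ub, b_ub, A_eq, lb, ub, integrality


def solve_reference_point(
    problem: MultiObjectiveProblem,
    bounds: CriteriaBounds,
    z_bar: np.ndarray,
    config: ScalarizationConfig | None = None,
    *,
    method: str = "reference_point",
) -> SolutionPoint:
    """Project a reference point onto the Pareto frontier.

    Maximizes the augmented achievement function over the feasible set by
    solving its scalarized program (auxiliary scalar ``z`` free in sign, so
    aspiration points above the feasible region remain well-posed) in
    lexicographic two-stage form: first maximize the min-term ``z``, then,
    with ``z`` held at its optimum, maximize the normalized sum
    ``sum_j lambda_j f_j``.  For any augmentation weight below the
    :func:`default_rho` bound the optimizer set of the one-shot augmented
    program coincides with the lexicographic one, but the two-stage solve is
    numerically robust where the one-shot program's rho-scaled coefficients
    would sink below solver tolerances.
    """
    config = config or ScalarizationConfig()
    z_bar = np.asarray(z_bar, dtype=float)
    if z_bar.shape != (problem.p,):
        raise ValueError(f"reference point must have length p={problem.p}")
    if not np.all(np.isfinite(z_bar)):
        raise ValueError("reference point components must be finite")
    rho = config.resolve_rho(bounds)
    obj_sum, A_ub, b_ub, A_eq, lb, ub, integrality = _assemble_rp(problem, bounds, z_bar)
    n_aug = obj_sum.size
    # stage 1: best attainable min-term
    obj_min = np.zeros(n_aug)
    obj_min[-1] = 1.0
    _, z_opt = solve_linear(
        obj_min,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=problem.b_eq,
        lb=lb,
        ub=ub,
        integrality=integrality,
        maximize=True,
        context="maximizing the achievement min-term",
        time_limit=config.time_limit,
    )
    # stage 2: among min-term optima, maximize the normalized criteria sum.
    # The coupling slack absorbs stage-1 solver tolerance: 1e-9 for pure LPs
    # (solved at 1e-10 feasibility), looser for MIPs — still far below the
    # scaled-criteria granularity of discrete instances, so it cannot admit a
    # strictly worse min-term lattice level.
    eps = 1e-6 if problem.is_mip else 1e-9
    lb2 = lb.copy()
    lb2[-1] = z_opt - eps * (1.0 + abs(z_opt))
    x_full, _ = solve_linear(
        obj_sum,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=problem.b_eq,
        lb=lb2,
        ub=ub,
        integrality=integrality,
        maximize=True,
        context="maximizing the augmentation sum at the optimal min-term",
        time_limit=config.time_limit,
    )
    x = x_full[:-1]
    ints = problem.integrality > 0
    x[ints] = np.round(x[ints])
    criteria = problem.exact_criteria(x)
    return SolutionPoint(
        decision=problem.decision_of(x),
        criteria=criteria,
        method=method,
        provenance={"reference_point": z_bar.tolist(), "rho": rho},
        achievement=achievement_value(criteria, z_bar, bounds, rho),
    )


def solve_weighted_sum(
    problem: MultiObjectiveProblem,
    weights: np.ndarray,
) -> SolutionPoint:
    """Maximize ``sum_j w_j f_j(x)`` (the classic a-priori aggregation baseline).

    Only supported points (on the convex hull of the frontier) are reachable
    this way; ties between optima are resolved by the solver.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (problem.p,):
        raise ValueError(f"weights must have length p={problem.p}")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be nonnegative and not all zero")
    x, _ = solve_linear(
        w @ problem.criteria,
        A_ub=problem.A_ub,
        b_ub=problem.b_ub,
        A_eq=problem.A_eq,
        b_eq=problem.b_eq,
        lb=problem.lb,
        ub=problem.ub,
        integrality=problem.integrality,
        maximize=True,
        context="solving weighted-sum scalarization",
    )
    ints = problem.integrality > 0
    x[ints] = np.round(x[ints])
    criteria = problem.exact_criteria(x)
    return SolutionPoint(
        decision=problem.decision_of(x),
        criteria=criteria,
        method="weighted_sum",
        provenance={"weights": w.tolist()},
        achievement=float(w @ criteria),
    )
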