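"""Dominance, non-dominance filtering, sampling baseline, frontier scanning.

The dominance relation is the component-wise one: ``z'`` dominates ``z`` when
``z' >= z`` in every criterion with at least one strict inequality.  The
filtering routine is the quadratic all-pairs comparison with the early-removal
optimization (a point declared dominated is removed from further comparisons),
adequate for the point-set sizes an interactive session produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .problem import MultiObjectiveProblem, SolutionPoint
from .scalarize import CriteriaBounds, ScalarizationConfig, solve_reference_point

__all__ = [
    "PointSet",
    "dominates",
    "filter_nondominated",
    "sample_explicit",
    "project_points",
    "scan_frontier_2d",
    "count_distinct",
]


@dataclass
class PointSet:
    """An ordered collection of solution points (or bare criteria vectors)."""

    points: list[SolutionPoint] = field(default_factory=list)

    @classmethod
    def from_criteria(cls, vectors: Iterable[Sequence[float]], method: str = "bare") -> "PointSet":
        return cls(
            [SolutionPoint(decision=np.zeros(0), criteria=np.asarray(v, float), method=method)
             for v in vectors]
        )

    @property
    def criteria(self) -> np.ndarray:
        """(n, p) array of criteria vectors."""
        if not self.points:
            return np.zeros((0, 0))
        return np.vstack([pt.criteria for pt in self.points])

    @property
    def p(self) -> int:
        arr = self.criteria
        return arr.shape[1] if arr.size else 0

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def __getitem__(self, i) -> SolutionPoint:
        return self.points[i]

    def append(self, point: SolutionPoint) -> None:
        if self.points and point.criteria.size != self.points[0].criteria.size:
            raise ValueError("all members of a PointSet must share the criteria dimension")
        self.points.append(point)

    # -- CSV round trip: method, p criteria columns, provenance JSON ------
    def to_frame(self) -> pd.DataFrame:
        import json

        p = self.p
        rows = []
        for pt in self.points:
            row = {"method": pt.method}
            for j in range(p):
                row[f"criterion_{j}"] = pt.criteria[j]
            row["provenance"] = json.dumps({k: _listify(v) for k, v in pt.provenance.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PointSet":
        import json

        df = pd.read_csv(path)
        crit_cols = [c for c in df.columns if c.startswith("criterion_")]
        pts = []
        for _, row in df.iterrows():
            prov = json.loads(row["provenance"]) if "provenance" in row and isinstance(row["provenance"], str) else {}
            pts.append(
                SolutionPoint(
                    decision=np.zeros(0),
                    criteria=row[crit_cols].to_numpy(dtype=float),
                    method=row.get("method", "bare"),
                    provenance=prov,
                )
            )
        return cls(pts)


def _listify(v):
    return v.tolist() if isinstance(v, np.ndarray) else v


def _as_array(points) -> np.ndarray:
    if isinstance(points, PointSet):
        return points.criteria
    return np.atleast_2d(np.asarray(points, dtype=float))


def dominates(z_prime: Sequence[float], z: Sequence[float]) -> bool:
    """True iff z' >= z componentwise with at least one strict inequality."""
    a = np.asarray(z_prime, dtype=float)
    b = np.asarray(z, dtype=float)
    if a.shape != b.shape:
        raise ValueError("criteria vectors must have equal length")
    return bool(np.all(a >= b) and np.any(a > b))


def filter_nondominated(points: PointSet | np.ndarray) -> PointSet | np.ndarray:
    """Members not dominated by any other member, in input order.

    All-pairs O(p n^2) comparison with early removal of dominated points.
    Exact duplicates of a non-dominated vector are all retained (duplicates
    never dominate each other).  Raises on empty input.
    """
    arr = _as_array(points)
    n = arr.shape[0]
    if n == 0:
        raise ValueError("cannot filter an empty point set")
    alive = np.ones(n, dtype=bool)
    # Scan in order of decreasing criteria sum: a dominator has a strictly
    # larger sum than anything it dominates, so when a point's turn comes and
    # it is still alive, nothing can dominate it later.  Each survivor then
    # removes everything it dominates in one vectorized sweep (the early
    # removal: dominated points never act as comparators).
    order = np.argsort(-arr.sum(axis=1), kind="stable")
    for i in order:
        if not alive[i]:
            continue
        a = arr[i]
        dominated = alive & (arr <= a).all(axis=1) & (arr < a).any(axis=1)
        alive[dominated] = False
    idx = np.flatnonzero(alive)
    if isinstance(points, PointSet):
        return PointSet([points[i] for i in idx])
    return arr[idx]


def sample_explicit(
    problem: MultiObjectiveProblem,
    n_samples: int,
    seed: int,
    retry_cap: int = 1000,
) -> PointSet:
    """The explicit baseline: n random feasible decisions with their criteria.

    Requires the problem's decision-sampler hook; each draw is rejection-checked
    against the constraints with a retry cap.
    """
    if problem.sampler is None:
        raise ValueError("problem exposes no decision-sampler hook")
    rng = np.random.default_rng(seed)
    out = PointSet()
    for k in range(n_samples):
        for attempt in range(retry_cap):
            x = np.asarray(problem.sampler(rng), dtype=float)
            if problem.is_feasible(x):
                break
        else:
            raise RuntimeError(
                f"sampler failed to produce a feasible decision within {retry_cap} tries "
                f"(sample {k})"
            )
        out.append(
            SolutionPoint(
                decision=problem.decision_of(x),
                criteria=problem.exact_criteria(x),
                method="explicit_sample",
                provenance={"seed": seed, "index": k},
            )
        )
    return out


def project_points(
    problem: MultiObjectiveProblem,
    bounds: CriteriaBounds,
    points: PointSet | np.ndarray,
    config: ScalarizationConfig | None = None,
) -> list[tuple[SolutionPoint, SolutionPoint]]:
    """Project each point onto the Pareto frontier via the reference-point solve.

    Each source criteria vector is used as the reference point; the projection
    is non-dominated and, for feasible sources, weakly improves every criterion.
    """
    if isinstance(points, PointSet):
        sources = list(points)
    else:
        sources = list(PointSet.from_criteria(_as_array(points)))
    pairs = []
    for src in sources:
        proj = solve_reference_point(problem, bounds, src.criteria, config, method="projection")
        pairs.append((src, proj))
    return pairs


def scan_frontier_2d(
    problem: MultiObjectiveProblem,
    bounds: CriteriaBounds,
    k: int,
    config: ScalarizationConfig | None = None,
) -> PointSet:
    """Sweep k reference points along the segment joining the frontier extremes.

    The extreme points A and B are computed lexicographically (maximize
    criterion 1 then 2, and 2 then 1) so each endpoint is itself non-dominated;
    the segment [A, B] is subdivided into k equally spaced reference points,
    endpoints included, and each is projected.  Bi-objective problems only.
    """
    if problem.p != 2:
        raise ValueError(f"frontier scanning requires p = 2 criteria, got p={problem.p}")
    if k < 2:
        raise ValueError("k must be >= 2")
    config = config or ScalarizationConfig()
    A = _lexmax_point(problem, bounds, first=0)
    B = _lexmax_point(problem, bounds, first=1)
    refs = np.linspace(A, B, k)
    out = PointSet()
    for z_bar in refs:
        out.append(solve_reference_point(problem, bounds, z_bar, config))
    return out


def _lexmax_point(problem, bounds, first: int) -> np.ndarray:
    """Lexicographic maximum: criterion `first`, then the other, as a z-vector.

    Implemented as one reference-point solve aspiring to the ideal value on the
    primary criterion and the anti-ideal on the secondary: the achievement
    min-term then enforces optimality of the primary criterion while the
    augmentation term pulls the secondary up to non-dominance.
    """
    other = 1 - first
    z_bar = np.empty(2)
    z_bar[first] = bounds.z_max[first]
    z_bar[other] = bounds.z_min[other]
    sol = solve_reference_point(problem, bounds, z_bar, ScalarizationConfig())
    return sol.criteria


def count_distinct(
    points: PointSet | np.ndarray,
    tolerance: float,
    scale: np.ndarray | None = None,
) -> int:
    """Number of equivalence classes under max-norm distance <= tolerance.

    ``scale`` (typically the lambda normalization weights) is applied before
    comparing, so the tolerance lives in scaled criteria space.  Transitive
    closure via union-find: chains of close points collapse into one class.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    arr = _as_array(points)
    n = arr.shape[0]
    if n == 0:
        return 0
    if scale is not None:
        arr = arr * np.asarray(scale, dtype=float)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.max(np.abs(arr[i] - arr[j])) <= tolerance:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    return len({find(i) for i in range(n)})
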