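"""Spatial resource allocation on a gridded landscape with 5 criteria.

A landscape is a grid of cells with an elevation field.  Water flows downhill:
each cell receives water from its highest strictly-higher 4-neighbor (its
*antecedent*); cells with no higher neighbor are peaks.  Managing a cell
(binary decision, under a budget and optionally a fixed number of managed
cells) increases its water retention time, adds a carbon-sequestration gain,
and saves individuals of each modelled species.

Criteria (all maximized):

* ``WTT`` — total water travel time, the sum over cells of the cumulative time
  for water to reach the cell along its antecedent chain; management slows
  runoff, so it increases WTT downstream.
* ``CS``  — carbon sequestration, the sum of per-cell gains over managed cells.
* ``N_S`` — saved individuals of species S, likewise additive.

The MILP formulation keeps the per-cell travel times ``T[i,j]`` as continuous
variables constrained by ``T <= T_antecedent + t + x d``; because every
criterion is maximized and the management increments ``d`` are nonnegative,
these inequalities are tight at any optimum, which the evaluation routine
re-verifies by exact recursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import uniform_filter

from .pareto import PointSet
from .problem import MultiObjectiveProblem, SolutionPoint

__all__ = [
    "LayerRanges",
    "Landscape",
    "generate_landscape",
    "compute_antecedents",
    "water_travel_time",
    "evaluate_criteria",
    "build_spatial_problem",
    "sample_random_decision",
    "enumerate_decisions",
]

_NEIGHBORS_4 = ((1, 0), (-1, 0), (0, 1), (0, -1))
_NEIGHBORS_8 = _NEIGHBORS_4 + ((1, 1), (1, -1), (-1, 1), (-1, -1))


@dataclass
class LayerRanges:
    """Uniform sampling ranges for the random landscape layers.

    Units are generic: time units for retention (t, d), mass for carbon (c),
    individuals for species headcounts (n), currency for costs.
    """

    t: tuple[float, float] = (1.0, 10.0)
    d: tuple[float, float] = (1.0, 10.0)
    c: tuple[float, float] = (1.0, 10.0)
    n: tuple[float, float] = (0.0, 20.0)
    cost: tuple[float, float] = (1.0, 10.0)
    elevation: tuple[float, float] = (0.0, 100.0)
    smoothing_window: int = 5
    budget_slack: float = 1.2
    integer_layers: bool = True  # integer-valued layers: criteria land on an integer lattice

    def validate(self) -> None:
        for name in ("t", "d", "c", "n", "cost", "elevation"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"empty range for layer {name!r}")


@dataclass
class Landscape:
    """Grid with elevation, runoff-antecedent forest and management layers."""

    elevation: np.ndarray
    antecedent: np.ndarray  # flat index of antecedent cell, -1 for peaks
    t: np.ndarray           # base retention time per cell
    d: np.ndarray           # additional retention when managed
    c: np.ndarray           # carbon gain when managed
    n: np.ndarray           # (n_species, rows, cols) individuals saved
    cost: np.ndarray
    budget: float
    K: int | None = None    # exact number of cells to manage (optional)
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.ndim != 2:
            raise ValueError("elevation must be a 2-d grid")
        shape = self.elevation.shape
        self.antecedent = np.asarray(self.antecedent, dtype=int)
        for name in ("t", "d", "c", "cost"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"layer {name!r} must match the grid shape")
            setattr(self, name, arr)
        self.n = np.asarray(self.n, dtype=float)
        if self.n.ndim != 3 or self.n.shape[1:] != shape:
            raise ValueError("species layers must have shape (n_species, rows, cols)")
        if np.any(self.d < 0) or np.any(self.c < 0) or np.any(self.n < 0):
            raise ValueError("d, c and n layers must be nonnegative")
        if np.any(self.cost <= 0):
            raise ValueError("costs must be strictly positive")
        _check_acyclic(self.elevation, self.antecedent)

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    @property
    def n_cells(self) -> int:
        return self.elevation.size

    @property
    def n_species(self) -> int:
        return self.n.shape[0]

    @property
    def n_criteria(self) -> int:
        return 2 + self.n_species

    def downstream_weights(self) -> np.ndarray:
        """For each cell, 1 + number of cells whose antecedent chain passes it.

        The exact algebraic reduction of WTT:
        ``WTT(x) = sum_k (t_k + x_k d_k) * w_k`` with these weights, because a
        cell's retention term enters the travel time of every cell downstream
        of it in the runoff forest.
        """
        flat_e = self.elevation.ravel()
        w = np.ones(self.n_cells)
        for i in np.argsort(flat_e, kind="stable"):  # children before ancestors
            a = self.antecedent.flat[i]
            if a >= 0:
                w[a] += w[i]
        return w


def _check_acyclic(elevation: np.ndarray, antecedent: np.ndarray) -> None:
    flat_e = elevation.ravel()
    ant = antecedent.ravel()
    if ant.shape != flat_e.shape:
        raise ValueError("antecedent map must match the grid shape")
    for i, a in enumerate(ant):
        if a >= 0 and flat_e[a] <= flat_e[i]:
            raise ValueError(
                "antecedent relation must strictly increase elevation "
                f"(cell {i} -> {a})"
            )


def compute_antecedents(
    elevation: np.ndarray,
    seed: int = 0,
    neighborhood: int = 4,
) -> np.ndarray:
    """Runoff antecedents: for each cell, its highest strictly-higher neighbor.

    Ties among several equally-highest higher neighbors are broken by a seeded
    random choice.  Cells with no strictly higher neighbor are peaks (-1), so
    the antecedent forest is acyclic by construction (elevation strictly
    increases along antecedent links).  Returns a flat-index grid.
    """
    e = np.asarray(elevation, dtype=float)
    rows, cols = e.shape
    offsets = _NEIGHBORS_4 if neighborhood == 4 else _NEIGHBORS_8
    rng = np.random.default_rng(seed)
    ant = np.full((rows, cols), -1, dtype=int)
    for i in range(rows):
        for j in range(cols):
            best = e[i, j]
            cands: list[int] = []
            for di, dj in offsets:
                ii, jj = i + di, j + dj
                if 0 <= ii < rows and 0 <= jj < cols and e[ii, jj] > e[i, j]:
                    if e[ii, jj] > best:
                        best = e[ii, jj]
                        cands = [ii * cols + jj]
                    elif e[ii, jj] == best:
                        cands.append(ii * cols + jj)
            if cands:
                ant[i, j] = cands[0] if len(cands) == 1 else cands[rng.integers(len(cands))]
    return ant


def generate_landscape(
    rows: int,
    cols: int,
    n_species: int = 3,
    seed: int = 0,
    ranges: LayerRanges | None = None,
    K: int | None = None,
    budget: float | None = None,
    neighborhood: int = 4,
) -> Landscape:
    """Seeded random landscape.

    Elevation is smoothed uniform noise (separable moving average, window from
    ``ranges``), which yields a small number of well-separated peaks; all other
    layers are independent uniforms on their configured ranges, drawn on the
    integer lattice by default (criteria are then integer-valued, which keeps
    the combinatorial granularity behind the rho bound meaningful and exact MIP
    optimality proofs cheap).  ``K`` defaults to one cell in 30 (120 on a 60x60
    grid).  The default budget is ``budget_slack * K * mean cell cost`` —
    generous enough that uniformly random K-subsets are almost surely
    affordable (the sampling baseline needs feasible random decisions) while
    remaining a binding constraint for expensive selections.
    """
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2x2")
    ranges = ranges or LayerRanges()
    ranges.validate()
    rng = np.random.default_rng(seed)
    lo, hi = ranges.elevation
    raw = rng.uniform(lo, hi, size=(rows, cols))
    elevation = uniform_filter(raw, size=ranges.smoothing_window, mode="nearest")
    antecedent = compute_antecedents(elevation, seed=seed, neighborhood=neighborhood)

    def draw(bounds_, size):
        if ranges.integer_layers:
            return rng.integers(int(bounds_[0]), int(bounds_[1]) + 1, size=size).astype(float)
        return rng.uniform(*bounds_, size=size)

    t = draw(ranges.t, (rows, cols))
    d = draw(ranges.d, (rows, cols))
    c = draw(ranges.c, (rows, cols))
    n = draw(ranges.n, (n_species, rows, cols))
    cost = draw(ranges.cost, (rows, cols))
    if K is None:
        K = max(1, (rows * cols) // 30)
    if budget is None:
        budget = ranges.budget_slack * K * float(cost.mean())
    return Landscape(
        elevation=elevation,
        antecedent=antecedent,
        t=t,
        d=d,
        c=c,
        n=n,
        cost=cost,
        budget=float(budget),
        K=K,
        seed=seed,
        meta={"ranges": ranges, "neighborhood": neighborhood},
    )


def _decision_array(landscape: Landscape, decision) -> np.ndarray:
    x = np.asarray(decision, dtype=float).reshape(landscape.shape)
    return x


def water_travel_time(landscape: Landscape, decision) -> tuple[float, np.ndarray]:
    """Exact travel times by recursion in topological (elevation) order.

    Peaks: ``T = t + x d``; other cells add their antecedent's travel time.
    Returns ``(WTT, T-grid)``.
    """
    x = _decision_array(landscape, decision).ravel()
    t = landscape.t.ravel()
    d = landscape.d.ravel()
    ant = landscape.antecedent.ravel()
    T = np.zeros(landscape.n_cells)
    order = np.argsort(-landscape.elevation.ravel(), kind="stable")  # high to low
    for i in order:
        T[i] = t[i] + x[i] * d[i] + (T[ant[i]] if ant[i] >= 0 else 0.0)
    return float(T.sum()), T.reshape(landscape.shape)


def evaluate_criteria(landscape: Landscape, decision, check_budget: bool = False) -> np.ndarray:
    """Criteria vector (WTT, CS, N_1..N_S) of a management decision."""
    x = _decision_array(landscape, decision)
    if check_budget and float((landscape.cost * x).sum()) > landscape.budget + 1e-7:
        raise ValueError("decision violates the budget constraint")
    wtt, _ = water_travel_time(landscape, x)
    cs = float((landscape.c * x).sum())
    ns = [float((landscape.n[s] * x).sum()) for s in range(landscape.n_species)]
    return np.asarray([wtt, cs, *ns])


def build_spatial_problem(
    landscape: Landscape,
    condense_travel_time: bool = False,
) -> MultiObjectiveProblem:
    """Compile the landscape into the budgeted multi-objective MILP.

    Variables: one binary ``x`` per cell, plus (default formulation) one
    continuous travel time ``T >= 0`` per cell with the antecedent-chain
    inequalities ``T_i - T_ant(i) - d_i x_i <= t_i``.  With
    ``condense_travel_time=True`` the travel-time variables are eliminated
    through the exact identity ``WTT(x) = sum_i (t_i + d_i x_i) w_i`` (with
    ``w`` the downstream-subtree weights), which halves the variable count and
    leaves a knapsack-like MILP that solves much faster; the two formulations
    have identical feasible criteria spaces.
    """
    N = landscape.n_cells
    cost = landscape.cost.ravel()
    t = landscape.t.ravel()
    d = landscape.d.ravel()
    c = landscape.c.ravel()
    ant = landscape.antecedent.ravel()
    p = landscape.n_criteria

    if condense_travel_time:
        n_vars = N
        w = landscape.downstream_weights()
        criteria = np.zeros((p, n_vars))
        offsets = np.zeros(p)
        criteria[0, :] = d * w
        offsets[0] = float((t * w).sum())
        A_ub = sp.csr_array(cost[None, :])
        b_ub = np.array([landscape.budget])
        integrality = np.ones(n_vars)
        ub = np.ones(n_vars)
        decision_mask = np.ones(n_vars, dtype=bool)
    else:
        n_vars = 2 * N  # [x cells, T cells]
        criteria = np.zeros((p, n_vars))
        offsets = np.zeros(p)
        criteria[0, N:] = 1.0  # WTT = sum T
        rows, cols_, vals, rhs = [], [], [], []
        r = 0
        rows += [r] * N
        cols_ += list(range(N))
        vals += cost.tolist()
        rhs.append(landscape.budget)
        r += 1
        for i in range(N):
            rows += [r, r]
            cols_ += [N + i, i]
            vals += [1.0, -d[i]]
            if ant[i] >= 0:
                rows.append(r)
                cols_.append(N + ant[i])
                vals.append(-1.0)
            rhs.append(t[i])
            r += 1
        A_ub = sp.csr_array((vals, (rows, cols_)), shape=(r, n_vars))
        b_ub = np.asarray(rhs)
        integrality = np.concatenate([np.ones(N), np.zeros(N)])
        ub = np.concatenate([np.ones(N), np.full(N, np.inf)])
        decision_mask = np.concatenate([np.ones(N, bool), np.zeros(N, bool)])

    criteria[1, :N] = c
    for s in range(landscape.n_species):
        criteria[2 + s, :N] = landscape.n[s].ravel()

    A_eq = b_eq = None
    if landscape.K is not None:
        row = np.zeros(n_vars)
        row[:N] = 1.0
        A_eq = sp.csr_array(row[None, :])
        b_eq = np.array([float(landscape.K)])

    def sampler(rng: np.random.Generator) -> np.ndarray:
        x = sample_random_decision(landscape, rng).ravel()
        return _full_vector(landscape, x, n_vars, N)

    def enumerator():
        for x in _iter_feasible_decisions(landscape):
            yield _full_vector(landscape, x, n_vars, N)

    return MultiObjectiveProblem(
        criteria=criteria,
        criteria_offsets=offsets,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        lb=np.zeros(n_vars),
        ub=ub,
        integrality=integrality,
        sampler=sampler,
        enumerator=enumerator,
        decision_mask=decision_mask,
        decision_criteria=lambda dec: evaluate_criteria(landscape, dec),
        meta={"kind": "spatial", "shape": landscape.shape, "condensed": condense_travel_time},
    )


def _full_vector(landscape: Landscape, x: np.ndarray, n_vars: int, N: int) -> np.ndarray:
    """Complete a cell decision with its tight travel times when T is modelled."""
    if n_vars == N:
        return x
    _, T = water_travel_time(landscape, x)
    return np.concatenate([x, T.ravel()])


def sample_random_decision(
    landscape: Landscape,
    rng: np.random.Generator | int,
    retry_cap: int = 1000,
) -> np.ndarray:
    """Uniformly random K-subset of cells, rejection-sampled against the budget."""
    if landscape.K is None:
        raise ValueError("sampling requires the landscape's K (number of managed cells)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    cost = landscape.cost.ravel()
    for _ in range(retry_cap):
        sel = rng.choice(landscape.n_cells, size=landscape.K, replace=False)
        if cost[sel].sum() <= landscape.budget + 1e-9:
            x = np.zeros(landscape.n_cells)
            x[sel] = 1.0
            return x.reshape(landscape.shape)
    raise RuntimeError(
        f"no affordable random {landscape.K}-subset found in {retry_cap} tries; "
        "the budget is too tight for the explicit baseline"
    )


def _iter_feasible_decisions(landscape: Landscape):
    N = landscape.n_cells
    cost = landscape.cost.ravel()
    K = landscape.K
    if K is None:
        raise ValueError("enumeration requires the landscape's K")
    for sel in combinations(range(N), K):
        if cost[list(sel)].sum() <= landscape.budget + 1e-9:
            x = np.zeros(N)
            x[list(sel)] = 1.0
            yield x


def enumerate_decisions(landscape: Landscape, cap: int = 100_000) -> PointSet:
    """Criteria vectors of every feasible K-subset (tiny instances only)."""
    K = landscape.K
    if K is None:
        raise ValueError("enumeration requires the landscape's K")
    total = comb(landscape.n_cells, K)
    if total > cap:
        raise ValueError(f"{total} candidate decisions exceed the cap of {cap}")
    out = PointSet()
    for x in _iter_feasible_decisions(landscape):
        out.append(
            SolutionPoint(
                decision=x.copy(),
                criteria=evaluate_criteria(landscape, x),
                method="enumerated_decision",
            )
        )
    return out
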