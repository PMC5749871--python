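"""Multi-objective finite-horizon Markov decision processes.

A finite-horizon MDP with one reward matrix per criterion is turned into a
multi-objective *linear* program over occupancy measures: the variable
``x[t, s, a]`` is the probability of being in state ``s`` and taking action
``a`` at step ``t`` under a (possibly randomized) Markov policy.  Flow
constraints anchor step 0 to the initial distribution and propagate mass from
step t-1 to step t through the transition kernel; criterion ``j`` is the
expected total reward ``sum_{t,s,a} R_j(s, a) x[t, s, a]``.

Because occupancy measures of Markov policies form a polytope, the criteria
region is the convex hull of the deterministic-policy points, and the
reference-point scalarization stays a pure LP (no integer variables).

The module also ships a seeded synthetic predator-prey generator (a stand-in,
with qualitatively matching structure, for classic two-species management
models: introduce predators / protect prey / cull predators / mixed action),
an occupancy-to-policy extractor, an exact dynamic-programming policy
evaluator, and a deterministic-policy enumerator for brute-force oracles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .pareto import PointSet
from .problem import MultiObjectiveProblem, SolutionPoint

__all__ = [
    "FiniteHorizonMDP",
    "MarkovPolicy",
    "build_momdp_problem",
    "occupancy_from_solution",
    "extract_policy",
    "evaluate_policy_dp",
    "generate_predator_prey_mdp",
    "generate_random_mdp",
    "enumerate_policy_points",
]

_STOCH_TOL = 1e-9


@dataclass
class FiniteHorizonMDP:
    """The tuple {S, A, T, Tr, {R_j}, mu0}.

    ``transitions[s, a, s2]`` is the probability of landing in ``s2`` after
    taking action ``a`` in state ``s``; every ``(s, a)`` row must sum to 1.
    ``rewards`` is a list of (n_states, n_actions) matrices, one per criterion.
    ``mu0`` is the initial state distribution.
    """

    transitions: np.ndarray
    rewards: list[np.ndarray]
    horizon: int
    mu0: np.ndarray
    state_labels: list[str] | None = None
    action_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        if self.transitions.ndim != 3 or self.transitions.shape[0] != self.transitions.shape[2]:
            raise ValueError("transitions must have shape (S, A, S)")
        S, A, _ = self.transitions.shape
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if np.any(self.transitions < -_STOCH_TOL) or np.any(self.transitions > 1 + _STOCH_TOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rowsums = self.transitions.sum(axis=2)
        if np.any(np.abs(rowsums - 1.0) > _STOCH_TOL):
            raise ValueError("every (state, action) transition row must sum to 1")
        self.rewards = [np.asarray(R, dtype=float) for R in self.rewards]
        if len(self.rewards) < 1:
            raise ValueError("need at least one reward matrix")
        for R in self.rewards:
            if R.shape != (S, A):
                raise ValueError("each reward matrix must have shape (S, A)")
        self.mu0 = np.asarray(self.mu0, dtype=float)
        if self.mu0.shape != (S,):
            raise ValueError("mu0 must have one entry per state")
        if np.any(self.mu0 < -_STOCH_TOL) or abs(self.mu0.sum() - 1.0) > _STOCH_TOL:
            raise ValueError("mu0 must be a probability distribution")

    @property
    def n_states(self) -> int:
        return self.transitions.shape[0]

    @property
    def n_actions(self) -> int:
        return self.transitions.shape[1]

    @property
    def n_criteria(self) -> int:
        return len(self.rewards)


@dataclass
class MarkovPolicy:
    """Time-dependent randomized policy: ``pi[t, s]`` is a distribution over actions."""

    pi: np.ndarray  # (T, S, A)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.ndim != 3:
            raise ValueError("pi must have shape (T, S, A)")
        if np.any(self.pi < -1e-12):
            raise ValueError("policy probabilities must be nonnegative")
        if np.any(np.abs(self.pi.sum(axis=2) - 1.0) > 1e-9):
            raise ValueError("each pi[t, s] must sum to 1")

    @classmethod
    def deterministic(cls, actions: np.ndarray, n_actions: int) -> "MarkovPolicy":
        """Build from an integer action table of shape (T, S)."""
        actions = np.asarray(actions, dtype=int)
        T, S = actions.shape
        pi = np.zeros((T, S, n_actions))
        for t in range(T):
            pi[t, np.arange(S), actions[t]] = 1.0
        return cls(pi)


def _occ_index(mdp: FiniteHorizonMDP):
    """Flat variable indexing for x[t, s, a]."""
    S, A, T = mdp.n_states, mdp.n_actions, mdp.horizon

    def idx(t, s, a):
        return (t * S + s) * A + a

    return idx, T * S * A


def build_momdp_problem(mdp: FiniteHorizonMDP) -> MultiObjectiveProblem:
    """Compile the MDP into the occupancy-measure multi-objective LP.

    Variables: x[t, s, a] >= 0.  Flow constraints (time-consistent form):
    ``sum_a x[0, s, a] = mu0(s)`` and, for t >= 1,
    ``sum_a x[t, s, a] = sum_{s', a} Tr(s', a, s) x[t-1, s', a]``.
    Criterion j is ``sum_{t,s,a} R_j(s, a) x[t, s, a]``.
    """
    S, A, T = mdp.n_states, mdp.n_actions, mdp.horizon
    idx, n = _occ_index(mdp)
    rows, cols, vals, rhs = [], [], [], []
    r = 0
    for s in range(S):  # t = 0 anchor
        for a in range(A):
            rows.append(r)
            cols.append(idx(0, s, a))
            vals.append(1.0)
        rhs.append(mdp.mu0[s])
        r += 1
    for t in range(1, T):  # flow conservation t-1 -> t
        for s in range(S):
            for a in range(A):
                rows.append(r)
                cols.append(idx(t, s, a))
                vals.append(1.0)
            for s2 in range(S):
                for a in range(A):
                    tr = mdp.transitions[s2, a, s]
                    if tr:
                        rows.append(r)
                        cols.append(idx(t - 1, s2, a))
                        vals.append(-tr)
            rhs.append(0.0)
            r += 1
    A_eq = sp.csr_array((vals, (rows, cols)), shape=(r, n))
    criteria = np.zeros((mdp.n_criteria, n))
    for j, R in enumerate(mdp.rewards):
        for t in range(T):
            for s in range(S):
                for a in range(A):
                    criteria[j, idx(t, s, a)] = R[s, a]
    return MultiObjectiveProblem(
        criteria=criteria,
        A_eq=A_eq,
        b_eq=np.asarray(rhs),
        lb=np.zeros(n),
        ub=np.full(n, np.inf),
        meta={"kind": "momdp", "shape": (T, S, A)},
    )


def occupancy_from_solution(mdp: FiniteHorizonMDP, solution: SolutionPoint | np.ndarray) -> np.ndarray:
    """Reshape a flat LP decision back into the (T, S, A) occupancy tensor."""
    x = solution.decision if isinstance(solution, SolutionPoint) else np.asarray(solution, float)
    T, S, A = mdp.horizon, mdp.n_states, mdp.n_actions
    return x.reshape(T, S, A)


def extract_policy(mdp: FiniteHorizonMDP, occupancy: np.ndarray) -> MarkovPolicy:
    """Normalize an occupancy tensor into a Markov policy.

    ``pi[t, s] = x[t, s, :] / sum_a x[t, s, a]``; (t, s) pairs with (numerically)
    zero visitation probability are unreachable under the policy and get the
    uniform distribution.
    """
    occ = np.asarray(occupancy, dtype=float)
    if occ.shape != (mdp.horizon, mdp.n_states, mdp.n_actions):
        raise ValueError("occupancy must have shape (T, S, A)")
    if np.any(occ < -1e-9):
        raise ValueError("occupancy entries must be nonnegative")
    occ = np.clip(occ, 0.0, None)
    totals = occ.sum(axis=2, keepdims=True)
    uniform = np.full(mdp.n_actions, 1.0 / mdp.n_actions)
    pi = np.where(totals > 1e-12, occ / np.where(totals > 1e-12, totals, 1.0), uniform)
    return MarkovPolicy(pi)


def evaluate_policy_dp(mdp: FiniteHorizonMDP, policy: MarkovPolicy) -> np.ndarray:
    """Exact expected total reward per criterion by forward propagation of mu0."""
    T, S, A = mdp.horizon, mdp.n_states, mdp.n_actions
    if policy.pi.shape != (T, S, A):
        raise ValueError("policy shape does not match the MDP")
    mu = mdp.mu0.copy()
    totals = np.zeros(mdp.n_criteria)
    for t in range(T):
        sa = mu[:, None] * policy.pi[t]  # joint P(s, a) at step t
        for j, R in enumerate(mdp.rewards):
            totals[j] += float((sa * R).sum())
        mu = np.einsum("sa,sax->x", sa, mdp.transitions)
    return totals


# ----------------------------------------------------------------------
# Synthetic generators
# ----------------------------------------------------------------------

def _birth_death_row(level: int, n_levels: int, p_up: float, p_down: float) -> np.ndarray:
    """Distribution over levels for a +1/0/-1 move with boundary clamping."""
    row = np.zeros(n_levels)
    p_up = float(np.clip(p_up, 0.0, 1.0))
    p_down = float(np.clip(p_down, 0.0, 1.0 - p_up))
    stay = 1.0 - p_up - p_down
    row[min(level + 1, n_levels - 1)] += p_up
    row[max(level - 1, 0)] += p_down
    row[level] += stay
    return row


def generate_predator_prey_mdp(
    n_prey_levels: int = 5,
    n_pred_levels: int = 5,
    horizon: int = 20,
    seed: int = 0,
) -> FiniteHorizonMDP:
    """Seeded two-species management MDP with genuinely conflicting criteria.

    States are (prey density level, predator abundance level) pairs on
    discretized grids.  Four management actions: introduce predators,
    enforce prey protection (anti-poaching), cull predators, and a half/half
    mixture.  Predation couples the species: higher predator levels depress
    prey growth and increase prey decline, so boosting one criterion erodes
    the other.  The two reward criteria are the normalized prey density and
    predator abundance of the occupied state (each criterion's single-step
    maximum is 1, so a horizon-T total lies in [0, T]).  Transition noise
    parameters are jittered reproducibly from ``seed``.
    """
    if n_prey_levels < 2 or n_pred_levels < 2:
        raise ValueError("need at least 2 levels per species")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    rng = np.random.default_rng(seed)
    S = n_prey_levels * n_pred_levels
    A = 4  # introduce, protect prey, cull, half/half

    def jitter():
        return rng.uniform(0.9, 1.1)

    # action-dependent baseline move probabilities
    prey_up_base = np.array([0.25, 0.55, 0.35, 0.45]) * jitter()
    prey_down_base = np.array([0.20, 0.08, 0.15, 0.11]) * jitter()
    pred_up_base = np.array([0.60, 0.15, 0.03, 0.09]) * jitter()
    pred_down_base = np.array([0.05, 0.15, 0.60, 0.38]) * jitter()
    predation = 0.65 * jitter()      # predator pressure on prey growth/decline
    prey_support = 0.55 * jitter()   # prey availability needed for predator growth

    transitions = np.zeros((S, A, S))
    R_prey = np.zeros((S, A))
    R_pred = np.zeros((S, A))
    for i in range(n_prey_levels):
        ifrac = i / (n_prey_levels - 1)
        for j in range(n_pred_levels):
            jfrac = j / (n_pred_levels - 1)
            s = i * n_pred_levels + j
            R_prey[s, :] = ifrac
            R_pred[s, :] = jfrac
            for a in range(A):
                prey_row = _birth_death_row(
                    i,
                    n_prey_levels,
                    prey_up_base[a] * (1.0 - predation * jfrac),
                    prey_down_base[a] + predation * 0.5 * jfrac,
                )
                pred_row = _birth_death_row(
                    j,
                    n_pred_levels,
                    pred_up_base[a] * (1.0 - prey_support * (1.0 - ifrac)),
                    pred_down_base[a] + 0.25 * (1.0 - ifrac),
                )
                joint = np.outer(prey_row, pred_row).ravel()
                transitions[s, a, :] = joint / joint.sum()
    labels = [f"prey{i}_pred{j}" for i in range(n_prey_levels) for j in range(n_pred_levels)]
    return FiniteHorizonMDP(
        transitions=transitions,
        rewards=[R_prey, R_pred],
        horizon=horizon,
        mu0=np.full(S, 1.0 / S),
        state_labels=labels,
        action_labels=["introduce_predators", "protect_prey", "cull_predators", "half_half"],
    )


def generate_random_mdp(
    n_states: int,
    n_actions: int,
    horizon: int,
    n_criteria: int = 2,
    seed: int = 0,
) -> FiniteHorizonMDP:
    """Dense random MDP (Dirichlet transition rows, uniform rewards) for tests."""
    rng = np.random.default_rng(seed)
    transitions = rng.dirichlet(np.ones(n_states), size=(n_states, n_actions))
    rewards = [rng.uniform(0, 1, size=(n_states, n_actions)) for _ in range(n_criteria)]
    mu0 = rng.dirichlet(np.ones(n_states))
    return FiniteHorizonMDP(transitions=transitions, rewards=rewards, horizon=horizon, mu0=mu0)


def enumerate_policy_points(mdp: FiniteHorizonMDP, cap: int = 100_000) -> PointSet:
    """Criteria vectors of every deterministic Markov policy (tiny instances).

    There are ``A ** (S * T)`` such policies; the call refuses instances above
    ``cap``.  The LP's feasible criteria region is the convex hull of these
    points (randomized policies mix them).
    """
    S, A, T = mdp.n_states, mdp.n_actions, mdp.horizon
    count = float(A) ** (S * T)
    if count > cap:
        raise ValueError(f"{count:.0f} deterministic policies exceed the cap of {cap}")
    out = PointSet()
    for assignment in itertools.product(range(A), repeat=S * T):
        actions = np.asarray(assignment, dtype=int).reshape(T, S)
        policy = MarkovPolicy.deterministic(actions, A)
        out.append(
            SolutionPoint(
                decision=actions.ravel().astype(float),
                criteria=evaluate_policy_dp(mdp, policy),
                method="enumerated_policy",
            )
        )
    return out
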