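"""Plain-text serialization for problems, MDPs, landscapes, decisions, policies.

Formats are deliberately boring: JSON/YAML for structured headers and small
dense arrays, one CSV grid per landscape layer, CSV for point sets (handled in
:mod:`refpoint.pareto`) and policies.  Everything round-trips losslessly at
float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .momdp import FiniteHorizonMDP, MarkovPolicy, generate_predator_prey_mdp
from .problem import MultiObjectiveProblem, from_point_list
from .spatial import Landscape, LayerRanges, generate_landscape

__all__ = [
    "problem_to_dict",
    "problem_from_dict",
    "save_mdp",
    "load_mdp",
    "save_landscape",
    "load_landscape",
    "save_policy_csv",
    "load_problem_config",
]


def problem_to_dict(problem: MultiObjectiveProblem) -> dict:
    """Generic linear problem as plain lists (criteria, constraint triplets, kinds)."""

    def dense(A):
        return np.asarray(A.todense()).tolist()

    return {
        "criteria": problem.criteria.tolist(),
        "criteria_offsets": problem.criteria_offsets.tolist(),
        "A_ub": dense(problem.A_ub),
        "b_ub": problem.b_ub.tolist(),
        "A_eq": dense(problem.A_eq),
        "b_eq": problem.b_eq.tolist(),
        "lb": problem.lb.tolist(),
        "ub": [None if not np.isfinite(v) else float(v) for v in problem.ub],
        "integrality": problem.integrality.tolist(),
        "names": list(problem.names) if problem.names else None,
    }


def problem_from_dict(d: dict) -> MultiObjectiveProblem:
    ub = np.asarray([np.inf if v is None else v for v in d["ub"]], dtype=float)
    offsets = d.get("criteria_offsets")
    return MultiObjectiveProblem(
        criteria=np.asarray(d["criteria"], dtype=float),
        criteria_offsets=None if offsets is None else np.asarray(offsets, dtype=float),
        A_ub=np.asarray(d["A_ub"], dtype=float) if d["A_ub"] else None,
        b_ub=np.asarray(d["b_ub"], dtype=float),
        A_eq=np.asarray(d["A_eq"], dtype=float) if d["A_eq"] else None,
        b_eq=np.asarray(d["b_eq"], dtype=float),
        lb=np.asarray(d["lb"], dtype=float),
        ub=ub,
        integrality=np.asarray(d["integrality"]),
        names=d.get("names"),
    )


def save_mdp(mdp: FiniteHorizonMDP, path: str | Path) -> None:
    """Dense JSON dump of the full tuple {Tr, R_j, T, mu0, labels}."""
    payload = {
        "transitions": mdp.transitions.tolist(),
        "rewards": [R.tolist() for R in mdp.rewards],
        "horizon": int(mdp.horizon),
        "mu0": mdp.mu0.tolist(),
        "state_labels": mdp.state_labels,
        "action_labels": mdp.action_labels,
    }
    Path(path).write_text(json.dumps(payload))


def load_mdp(path: str | Path) -> FiniteHorizonMDP:
    d = json.loads(Path(path).read_text())
    return FiniteHorizonMDP(
        transitions=np.asarray(d["transitions"], dtype=float),
        rewards=[np.asarray(R, dtype=float) for R in d["rewards"]],
        horizon=int(d["horizon"]),
        mu0=np.asarray(d["mu0"], dtype=float),
        state_labels=d.get("state_labels"),
        action_labels=d.get("action_labels"),
    )


_GRID_LAYERS = ("elevation", "t", "d", "c", "cost")


def save_landscape(landscape: Landscape, directory: str | Path) -> None:
    """One CSV grid per layer plus a JSON header (dims, budget, K, seed)."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    for name in _GRID_LAYERS:
        np.savetxt(out / f"{name}.csv", getattr(landscape, name), delimiter=",")
    np.savetxt(out / "antecedent.csv", landscape.antecedent, delimiter=",", fmt="%d")
    for s in range(landscape.n_species):
        np.savetxt(out / f"species_{s + 1}.csv", landscape.n[s], delimiter=",")
    header = {
        "rows": landscape.shape[0],
        "cols": landscape.shape[1],
        "n_species": landscape.n_species,
        "budget": landscape.budget,
        "K": landscape.K,
        "seed": landscape.seed,
    }
    (out / "landscape.json").write_text(json.dumps(header, indent=2))


def load_landscape(directory: str | Path) -> Landscape:
    src = Path(directory)
    header = json.loads((src / "landscape.json").read_text())
    layers = {
        name: np.loadtxt(src / f"{name}.csv", delimiter=",", ndmin=2)
        for name in _GRID_LAYERS
    }
    antecedent = np.loadtxt(src / "antecedent.csv", delimiter=",", ndmin=2).astype(int)
    n = np.stack(
        [
            np.loadtxt(src / f"species_{s + 1}.csv", delimiter=",", ndmin=2)
            for s in range(header["n_species"])
        ]
    )
    return Landscape(
        elevation=layers["elevation"],
        antecedent=antecedent,
        t=layers["t"],
        d=layers["d"],
        c=layers["c"],
        n=n,
        cost=layers["cost"],
        budget=header["budget"],
        K=header["K"],
        seed=header.get("seed"),
    )


def save_policy_csv(policy: MarkovPolicy, path: str | Path) -> None:
    """Long-format policy table: t, state, action, probability."""
    T, S, A = policy.pi.shape
    rows = [
        {"t": t, "state": s, "action": a, "probability": policy.pi[t, s, a]}
        for t in range(T)
        for s in range(S)
        for a in range(A)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_problem_config(path: str | Path):
    """Build a problem (and its context object) from a declarative YAML config.

    Supported kinds::

        kind: predator_prey_mdp    # n_prey_levels, n_pred_levels, horizon, seed
        kind: mdp_file             # path (JSON written by save_mdp)
        kind: landscape            # rows, cols, n_species, seed, K, budget, ...
        kind: landscape_dir        # path (directory written by save_landscape)
        kind: discrete_points      # points: [[...], ...]

    Returns ``(problem, context)`` where context is the MDP / Landscape / None.
    """
    from .momdp import build_momdp_problem
    from .spatial import build_spatial_problem

    cfg = yaml.safe_load(Path(path).read_text())
    kind = cfg.pop("kind")
    if kind == "predator_prey_mdp":
        mdp = generate_predator_prey_mdp(**cfg)
        return build_momdp_problem(mdp), mdp
    if kind == "mdp_file":
        mdp = load_mdp(cfg["path"])
        return build_momdp_problem(mdp), mdp
    if kind == "landscape":
        condense = cfg.pop("condense_travel_time", False)
        ranges = cfg.pop("ranges", None)
        if ranges is not None:
            ranges = LayerRanges(**{k: tuple(v) if isinstance(v, list) else v for k, v in ranges.items()})
        landscape = generate_landscape(ranges=ranges, **cfg)
        return build_spatial_problem(landscape, condense_travel_time=condense), landscape
    if kind == "landscape_dir":
        condense = cfg.pop("condense_travel_time", False)
        landscape = load_landscape(cfg["path"])
        return build_spatial_problem(landscape, condense_travel_time=condense), landscape
    if kind == "discrete_points":
        return from_point_list(cfg["points"]), None
    raise ValueError(f"unknown problem kind {kind!r}")
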