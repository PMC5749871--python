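"""Interactive reference-point sessions and the two batch comparison drivers.

The interactive loop mirrors how a decision-maker uses the method: the tool
reports the attainable range of every criterion, the user states an aspiration
point, the solver returns the closest efficient solution, and the user refines
the aspiration until satisfied.  The batch drivers reproduce, at configurable
scale, the two standard comparisons: reference points versus weighted sums on
a bi-objective MDP, and projection of randomly sampled decisions versus the
samples themselves on the spatial problem.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pareto import (
    PointSet,
    count_distinct,
    filter_nondominated,
    project_points,
    sample_explicit,
    scan_frontier_2d,
)
from .problem import MultiObjectiveProblem, SolutionPoint
from .scalarize import (
    CriteriaBounds,
    ScalarizationConfig,
    compute_bounds,
    solve_reference_point,
    solve_weighted_sum,
)
from .solver import SOLVER_IDENTITY

__all__ = [
    "SessionState",
    "run_interactive_session",
    "weight_grid_2d",
    "run_mdp_comparison",
    "run_spatial_comparison",
]


@dataclass
class SessionState:
    """State of an interactive session: bounds, config, and the iteration history."""

    problem: MultiObjectiveProblem
    bounds: CriteriaBounds
    config: ScalarizationConfig
    history: list[tuple[np.ndarray, SolutionPoint]] = field(default_factory=list)


def run_interactive_session(
    problem: MultiObjectiveProblem,
    config: ScalarizationConfig | None = None,
    istream=None,
    ostream=None,
    criteria_names: list[str] | None = None,
) -> SessionState:
    """Prompt-solve-display loop over reference points.

    Reads whitespace/comma-separated reference points from ``istream`` (default
    stdin) until ``q``/``quit``/EOF; malformed or wrong-dimension input is
    re-prompted, not fatal.  Returns the full session history.
    """
    import sys

    istream = istream or sys.stdin
    ostream = ostream or sys.stdout
    config = config or ScalarizationConfig()

    def say(msg: str) -> None:
        ostream.write(msg + "\n")

    bounds = compute_bounds(problem)
    p = problem.p
    names = criteria_names or [f"criterion_{j}" for j in range(p)]
    say("Attainable criterion ranges (anti-ideal .. ideal):")
    for j in range(p):
        say(f"  {names[j]}: {bounds.z_min[j]:.6g} .. {bounds.z_max[j]:.6g}")
    state = SessionState(problem=problem, bounds=bounds, config=config)
    say(f"Enter a reference point ({p} values), or q to quit.")
    while True:
        ostream.write("z> ")
        ostream.flush()
        line = istream.readline()
        if not line:
            break
        line = line.strip()
        if line.lower() in {"q", "quit", "exit"}:
            break
        if not line:
            continue
        try:
            z_bar = np.asarray([float(tok) for tok in line.replace(",", " ").split()])
        except ValueError:
            say("Could not parse that as numbers; try again.")
            continue
        if z_bar.size != p:
            say(f"Expected {p} values, got {z_bar.size}; try again.")
            continue
        sol = solve_reference_point(problem, bounds, z_bar, config)
        say("Efficient solution found:")
        for j in range(p):
            say(f"  {names[j]}: aspired {z_bar[j]:.6g} -> achieved {sol.criteria[j]:.6g}")
        say(f"  achievement: {sol.achievement:.6g}")
        state.history.append((z_bar, sol))
    return state


def weight_grid_2d(k: int) -> np.ndarray:
    """k equally spaced weight pairs from (0, 1) to (1, 0), endpoints included."""
    if k < 2:
        raise ValueError("k must be >= 2")
    s = np.linspace(0.0, 1.0, k)
    return np.column_stack([s, 1.0 - s])


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def run_mdp_comparison(
    problem: MultiObjectiveProblem,
    k: int = 20,
    config: ScalarizationConfig | None = None,
    out_path: str | Path | None = None,
    bounds: CriteriaBounds | None = None,
) -> dict:
    """Weighted-sum grid versus reference-point frontier scan on a bi-objective problem.

    Runs k equally spaced weight pairs and k reference points along the segment
    joining the frontier extremes, counts distinct points in each set (scaled
    max-norm tolerance from the config), and writes both point sets plus a JSON
    summary when ``out_path`` is given.  The reference-point scan can never
    yield fewer distinct non-dominated points than the weighted-sum grid.
    """
    if problem.p != 2:
        raise ValueError("the comparison driver is bi-objective")
    config = config or ScalarizationConfig()
    bounds = bounds if bounds is not None else compute_bounds(problem)
    ws = PointSet([solve_weighted_sum(problem, w) for w in weight_grid_2d(k)])
    rp = scan_frontier_2d(problem, bounds, k, config)
    ws_distinct = count_distinct(ws, config.distinct_tol, scale=bounds.lam)
    rp_distinct = count_distinct(rp, config.distinct_tol, scale=bounds.lam)
    if rp_distinct < ws_distinct:
        raise AssertionError(
            "reference-point scan produced fewer distinct points than the "
            f"weighted-sum grid ({rp_distinct} < {ws_distinct})"
        )
    report = {
        "k": k,
        "ws_distinct": ws_distinct,
        "rp_distinct": rp_distinct,
        "solver": SOLVER_IDENTITY,
        "config_hash": _config_hash({"k": k, "rho": config.rho, "tol": config.distinct_tol}),
        "z_max": bounds.z_max.tolist(),
        "z_min": bounds.z_min.tolist(),
    }
    if out_path is not None:
        out = Path(out_path)
        out.mkdir(parents=True, exist_ok=True)
        ws.to_csv(out / "weighted_sum_points.csv")
        rp.to_csv(out / "reference_point_points.csv")
        (out / "summary.json").write_text(json.dumps(report, indent=2))
    report["ws_points"] = ws
    report["rp_points"] = rp
    return report


def run_spatial_comparison(
    problem: MultiObjectiveProblem,
    n_samples: int,
    n_keep: int,
    seed: int,
    config: ScalarizationConfig | None = None,
    out_path: str | Path | None = None,
    bounds: CriteriaBounds | None = None,
) -> dict:
    """The explicit-sampling baseline versus its reference-point projection.

    Samples ``n_samples`` random feasible decisions, keeps the mutually
    non-dominated ones (at most ``n_keep``), projects each onto the Pareto
    frontier using itself as the reference point, and reports the per-criterion
    mean relative improvement.  Every feasible source must be weakly improved
    on every criterion (achievement >= 0), which the driver asserts.
    """
    config = config or ScalarizationConfig()
    bounds = bounds if bounds is not None else compute_bounds(problem)
    samples = sample_explicit(problem, n_samples, seed)
    kept = filter_nondominated(samples)
    if len(kept) > n_keep:
        kept = PointSet(list(kept)[:n_keep])
    pairs = project_points(problem, bounds, kept, config)
    p = problem.p
    rel = np.empty((len(pairs), p))
    for i, (src, proj) in enumerate(pairs):
        if np.any(proj.criteria < src.criteria - 1e-6):
            raise AssertionError(
                f"projection of pair {i} lost ground on a criterion: "
                f"{src.criteria} -> {proj.criteria}"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            rel[i] = np.where(
                src.criteria != 0,
                (proj.criteria - src.criteria) / np.abs(src.criteria),
                np.nan,
            )
    mean_rel = np.nanmean(rel, axis=0) if len(pairs) else np.full(p, np.nan)
    report = {
        "n_samples": n_samples,
        "n_kept": len(kept),
        "seed": seed,
        "solver": SOLVER_IDENTITY,
        "config_hash": _config_hash(
            {"n_samples": n_samples, "n_keep": n_keep, "seed": seed, "rho": config.rho}
        ),
        "mean_relative_improvement": mean_rel.tolist(),
        "mean_relative_improvement_pooled": float(np.nanmean(rel)) if len(pairs) else float("nan"),
    }
    if out_path is not None:
        out = Path(out_path)
        out.mkdir(parents=True, exist_ok=True)
        _write_pairs_csv(out / "pairs.csv", pairs)
        (out / "summary.json").write_text(
            json.dumps({k: v for k, v in report.items()}, indent=2)
        )
    report["pairs"] = pairs
    return report


def _write_pairs_csv(path: Path, pairs) -> None:
    import pandas as pd

    rows = []
    for i, (src, proj) in enumerate(pairs):
        row = {"pair": i}
        for j, v in enumerate(src.criteria):
            row[f"source_{j}"] = v
        for j, v in enumerate(proj.criteria):
            row[f"projection_{j}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
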