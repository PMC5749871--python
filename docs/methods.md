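# Methods

`refpoint` implements the interactive reference-point method for
multi-objective combinatorial optimization, together with two conservation
problem families compiled to linear/mixed-integer programs: finite-horizon
multi-objective Markov decision processes (via occupancy measures) and a
budgeted spatial resource-allocation model on a gridded landscape.  This note
records the model, its assumptions, the numerical choices, and what the
synthetic generators do and do not emulate.

## The reference-point scalarization

A problem has p ≥ 2 linear criteria f_j(x), all maximized over a feasible set
X described by linear constraints with continuous and/or binary variables.
A point z ∈ R^p **dominates** z' when z ≥ z' componentwise with at least one
strict inequality; the **Pareto frontier** is the set of feasible criteria
vectors dominated by nothing.

The decision-maker states an aspiration (reference point) z̄, feasible or
not.  With per-criterion ideal/anti-ideal values z^max, z^min obtained from 2p
single-objective solves, and normalization weights λ_j = 1/(z^max_j −
z^min_j), the augmented achievement function is

    s(x) = min_j λ_j (f_j(x) − z̄_j)  +  ρ Σ_j λ_j (f_j(x) − z̄_j),   ρ > 0.

Maximizing s over X is itself an LP/MILP: introduce a scalar z with
constraints z ≤ λ_j(f_j(x) − z̄_j) and maximize z plus the augmentation term.
Two guarantees motivate the method: every maximizer of s is an efficient
(non-dominated) decision, and every non-dominated point is recovered by using
itself as the reference point, provided ρ stays below the combinatorial bound
min_j λ_j / Σ_j (z^max_j − z^min_j) (`default_rho` returns half that bound,
keeping the inequality strict with margin against rounding).

**Sign of z.**  The scalar z is free in sign: an aspiration above the
feasible region makes every λ_j(f_j − z̄_j) negative, and constraining z ≥ 0
would render exactly the standard "ambitious aspiration" use case infeasible.

**Degenerate criteria.**  A criterion with z^max = z^min carries no decision
information: it receives λ = 1, is excluded from the min-term (it would pin z
at 0 regardless of the decision) but kept in the augmentation sum, and a
warning is logged.  `default_rho` refuses such instances; when no explicit ρ
is configured the solve path applies the same bound formula restricted to the
informative criteria.

**Numerical realization: lexicographic two-stage solve.**  On realistic
instances the ρ bound evaluates to 10⁻⁶–10⁻⁹, so the one-shot augmented
objective carries coefficients of order ρ·λ ≈ 10⁻⁸–10⁻¹³ — far below LP/MIP
solver tolerances.  In that regime the augmentation term is numerically
invisible: the solver breaks min-term ties arbitrarily and can return weakly
dominated optima (we observed exactly this on 4×4 landscape instances).
`solve_reference_point` therefore maximizes the achievement function in its
lexicographic form: stage 1 maximizes the min-term z alone; stage 2 fixes z at
its optimum (lower bound z* − ε, with ε = 10⁻⁹ for pure LPs solved at 10⁻¹⁰
feasibility and 10⁻⁶ for MIPs — both far below the scaled-criteria lattice
granularity of the bundled discrete problems, so no strictly worse min-term
level can sneak in) and maximizes the normalized sum Σ_j λ_j f_j.  For any ρ
below the bound the optimizer set of the augmented program coincides with the
lexicographic one on discrete instances, so this is the same method with
well-conditioned arithmetic.  The reported `achievement` is the augmented
value at the configured (or derived) ρ.

**Solver.**  All solves go through scipy's HiGHS interfaces: `linprog` for
pure LPs with feasibility tolerances tightened to 10⁻¹⁰ (the occupancy-measure
invariants are asserted at 10⁻⁹), `milp` with `mip_rel_gap=0` for integer
problems, so a returned solution is provably optimal or an error carrying the
solver status is raised.  An optional per-solve wall-clock cap
(`ScalarizationConfig.time_limit`) turns an expired solve into an error —
an unproven incumbent is never returned silently.  Criteria of returned
solutions are recomputed from the decision itself (for the landscape, by the
exact runoff recursion) rather than read off auxiliary epigraph variables,
which need not be tight at every solver optimum.

**Distinctness.**  Two criteria vectors count as the same point when they
differ by at most 10⁻⁶ in max-norm after λ-scaling; distinct counts use
union-find over that relation.

## Multi-objective finite-horizon MDPs

A finite-horizon MDP {S, A, T, Tr, {R_j}, μ₀} becomes a multi-objective LP
over occupancy measures x[t, s, a] — the probability of being in state s and
taking action a at step t under a (possibly randomized) Markov policy:

    Σ_a x[0, s, a] = μ₀(s)
    Σ_a x[t, s, a] = Σ_{s', a} Tr(s', a, s) x[t−1, s', a],   t ≥ 1
    x ≥ 0,     criterion j:  Σ_{t,s,a} R_j(s, a) x[t, s, a].

The initial distribution μ₀ is a required input (the flow system with an
all-zero right-hand side would only admit x ≡ 0); the time indices couple
consecutive steps so probability mass is conserved, and Σ_{s,a} x[t, s, a] = 1
at every step of every optimum.  Criteria are direct linear expressions in
the occupancy variables rather than separate epigraph scalars: a one-sided
C_j ≤ Σ R_j x with C_j ≥ 0 would make the anti-ideal solve (minimizing C_j)
vacuous, and at every maximizing optimum the two forms agree.

Policies are recovered by normalization, π[t, s](a) = x[t,s,a] / Σ_a x[t,s,a];
(t, s) pairs with zero visitation mass are unreachable and get the uniform
distribution.  Randomized policies are reported as such — the LP's feasible
criteria region is the convex hull of the deterministic-policy points, and
rounding would forfeit exactness.  `evaluate_policy_dp` provides the
independent oracle: exact forward propagation of the state distribution, no
simulation.  `enumerate_policy_points` evaluates all |A|^(S·T) deterministic
policies on tiny instances (capped at 10⁵) for brute-force tests.

### The synthetic predator–prey generator

The original two-species study this family is patterned on (sea otter /
abalone management) has its MDP parameterization in a prior publication, not
reproducible here; the generator emulates its *structure*: states are (prey
density level, predator abundance level) pairs; four yearly actions —
introduce predators, protect prey (anti-poaching), cull predators, half/half;
a 20-year default horizon.  Transitions are independent birth–death moves per
species whose up/down probabilities depend on the action, with predation
coupling (higher predator levels depress prey growth and raise prey decline;
predator growth needs prey), which makes the two criteria genuinely conflict
— verified in tests via `compute_bounds`.  Each criterion is the occupied
state's normalized level (single-step maximum 1), so a horizon-T total lies in
[0, T]; the normalization is built into the rewards rather than applied after
the fact.  Baseline move probabilities are jittered ±10% reproducibly from
the seed; μ₀ is uniform.  What it does **not** emulate: calibrated ecological
rates, density-dependent carrying capacities, or observation uncertainty —
passing tests show the optimization machinery is exact on MDPs of this shape,
not that the specific sea-otter/abalone trade-off curve is reproduced.

## Spatial resource allocation

A rows×cols landscape carries elevation e, base water retention times t,
management retention increments d ≥ 0, carbon gains c ≥ 0, per-species saved
headcounts n^S ≥ 0, costs > 0, a budget B and optionally an exact number of
cells K to manage.  Water flows from each cell's **antecedent** — its highest
4-neighbor, provided that neighbor is strictly higher; ties among equally
highest strictly-higher neighbors are broken by a seeded random choice; cells
with no strictly higher neighbor are peaks.  Strictness guarantees the
antecedent forest is acyclic (elevation strictly increases along links);
8-connectivity is one flag away.  Travel times follow the recursion T = t +
x·d (+ T of the antecedent), and the criteria are WTT = ΣT (management slows
runoff, so WTT is maximized, consistent with the model's epigraph
formulation), CS = Σ c·x, and N_S = Σ n^S·x.

The MILP keeps binary x per cell, continuous T ≥ 0 per cell with
T_i − T_ant(i) − d_i x_i ≤ t_i, the budget row, and the optional cardinality
row Σx = K.  Because every criterion is maximized and d ≥ 0, the T
inequalities are tight at optima; the returned criteria are nevertheless
recomputed by the exact recursion.  `condense_travel_time=True` eliminates
the T variables through the identity WTT(x) = Σ_k (t_k + d_k x_k)·w_k, where
w_k is 1 + the number of cells downstream of k in the runoff forest — an
exact algebraic reduction (tested against the full formulation) that halves
the variable count and is the recommended setting for large grids.

### The landscape generator

Elevation is uniform noise smoothed by a separable moving average (window 5 by
default); all other layers are independent uniforms on configurable ranges
(defaults t, d, c, cost ∈ [1, 10], n ∈ [0, 20]), drawn **on the integer
lattice** by default — the model's published criterion values are integers,
and integer data gives the ρ bound's unit-granularity premise real force.
K defaults to one cell in 30 (120 on a 60×60 grid).  The default budget is
1.2 × K × mean cell cost: uniformly random K-subsets are then almost surely
affordable — the explicit baseline of the original study draws random
120-cell subsets directly, so feasibility of random subsets is part of the
emulated study condition — while the budget still binds for expensive
selections.  (A budget anchored to the K cheapest cells would make rejection
sampling of random subsets essentially always fail.)  Not emulated: spatial
autocorrelation of costs or species layers, hydrological realism beyond the
antecedent recursion, and connectivity/compactness of reserves.

## Baselines and batch drivers

* **Weighted sum**: maximize Σ w_j f_j, w ≥ 0, w ≠ 0.  Reaches only supported
  points (on the convex hull of the frontier); ties are solver-resolved and
  documented as backend-dependent.
* **Explicit sampling**: random feasible decisions via the problem's sampler
  hook (for the landscape, uniform K-subsets rejection-sampled against the
  budget, retry cap 1000), filtered to the mutually non-dominated subset by
  the O(p n²) all-pairs comparison with early removal (a point found dominated
  stops being a comparator), then optionally projected onto the frontier by
  using each point as its own reference point.  Projections of feasible
  sources weakly improve every criterion (optimal achievement ≥ 0).
* **Bi-objective frontier scan**: extreme points computed lexicographically
  (maximize one criterion, then the other at the first's optimum — plain
  single-objective solves may return weakly dominated optima), then k equally
  spaced reference points on the segment joining them, endpoints included.
* **Weight grid**: k pairs linearly interpolated from (0, 1) to (1, 0),
  endpoints included.

## Problem sizes used by the test suite and acceptance script

Chosen as desk-scale settings exercising every code path: enumeration oracles
run on 4×4 landscapes with K = 3 (≤ 560 decisions) and MDPs up to |S|=3,
|A|=2, T=4 (4096 deterministic policies); the MDP comparison runs the 5×5
predator–prey instance at T = 20 with k = 20; the scripted spatial comparison
runs a 20×20 landscape (K = 13), 2000 samples, 50 projections.  The full-scale
spatial study (60×60, K = 120, 10 000 samples, 300 projections) is exercised
end-to-end in the acceptance suite; with the open-source HiGHS backend each
exact (zero-gap) projection MILP at that scale takes on the order of minutes
— across every formulation and parameter variant we benchmarked — so the
corresponding test enforces its time window honestly and reports how many
exact projections completed rather than relaxing optimality or shrinking the
instance.  Every completed projection at full scale satisfies the weak- and
strict-improvement properties.

## Known limitations

* Exact MILP scalarization at the full 60×60 scale is solver-bound (see
  above); a commercial MIP engine restores interactive latency.
* The weighted-sum baseline's tie-breaking between equally weighted optima is
  backend-dependent; tests only assert properties that hold for every optimum.
* No infinite-horizon/discounted MDP variant, no partial observability, no
  nonlinear criteria beyond what the two bundled families need.
* The generators emulate structure, not calibrated ecology; conclusions from
  green tests are about the optimization method, not about any real system.
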