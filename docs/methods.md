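# Methods

## Model and problem

A temporal network is a sequence of undirected, simple, unweighted
snapshots G₁..Gₜ over one fixed node set; only edges change between time
points.  Given a query 𝒢¹ (|V¹| = m) and a target 𝒢² (|V²| = n ≥ m) with
the same number of time points, we seek one injective mapping
ψ : V¹ → V² maximising

  score(𝒢¹, 𝒢² | ψ) = Σᵢ [ Σᵤ Sᵢ(u, ψ(u)) − δ·(NCCᵢ − 1) ],

where NCCᵢ is the number of connected components of the induced
subnetwork of the image Ψ(V¹) in G²ᵢ (isolated aligned nodes each count
as one component) and δ charges each edge insertion that would be needed
to connect them.  The query is assumed connected at every time point; an
empty query is rejected rather than scored.

## Similarity scores

Per time point, the pair operator Aᵢ[(u,v),(w,z)] = 1/(|N(w)|·|N(z)|) for
w ∈ N(u), z ∈ N(v) (else 0) is column stochastic on columns whose two
nodes both have positive degree; isolated-node columns are left all-zero
(no teleportation).  Homology is mixed in by iterating
Hʳ = α·Aᵢ·Hʳ⁻¹ + (1 − α)·H⁰, a contraction for α < 1 whose fixed point
solves (I − αAᵢ)x = (1 − α)h⁰.  Numerical choices:

* **α = 0.7** by default; α = 0 reduces to pure homology, exactly.
* **H⁰ normalisation**: the raw homology matrix is scaled to sum to 1
  before iteration, making the stopping tolerance scale-free; the scale
  factor is recorded on the `ScoreSet` so any quantity derived from the
  scores (e.g. the default δ) lives on one consistent scale.
* **Stopping rule**: exact fixed-point equality is unattainable in
  floating point, so iteration stops at max-norm change ≤ 1e-9 (default)
  or 200 iterations, returning a convergence flag (a warning, not an
  error, on non-convergence).
* The operator is applied matrix-free as B₁(X ⊘ d₁d₂ᵀ)B₂ with sparse
  adjacency matrices; tests materialise the dense (mn × mn) matrix only
  as an oracle.

Scores are aggregated as S = Σᵢ Sᵢ.  Missing homology pairs default to 0,
so the bipartite graph used below is complete.

## Phase 1 — initial matching

ψ₀ is the maximum-weight injective assignment under S, computed with the
Hungarian algorithm (`scipy.optimize.linear_sum_assignment`) over rows
and columns in sorted label order, which fixes tie-breaking across
platforms.  Target nodes outside the image form the gap set F.

## Phase 2 — swap selection

A swap replaces an aligned target node with a gap node, leaving the rest
of ψ intact.  Selecting the ≤ k swaps minimising the component penalty is
NP-hard — `mcp_reduction` encodes Maximum Coverage so that after k swaps
the component count is β = (m + n − k + 1) − τ with τ the covered
elements — so selection is heuristic:

* **Branches.** For every aligned target node uᵢ, `solution(r, uᵢ)` is the
  best known size-r swap set containing a swap of uᵢ.  Iteration 1 scans
  every (uᵢ, v ∈ F) pair; iteration r extends any `solution(r−1, uⱼ)` by
  one pair (uᵢ, vᵢ) subject to feasibility: vᵢ ∈ F, uᵢ not already
  swapped in the base set, vᵢ not already used in it.
* **Carry-forward.** If every feasible extension of a branch would lower
  its score, the branch keeps its size-(r−1) set.  Together with the
  final argmax including the empty set, this makes the recorded best
  score non-decreasing in r and the returned score ≥ the initial score —
  the guarantee that holds whenever δ ≥ every per-time pair score.  A
  user-supplied δ below that threshold triggers a warning.
* **Default δ** is max S(u,v); since per-time scores are non-negative and
  sum to the aggregate, it dominates every Sᵢ(u,v).
* **Default k** is the worst-time-point NCC of the initial image minus
  one (floored at 1, capped at |F|); the max over time points was chosen
  because a single fragmented time point already determines how many
  merges could possibly pay off.
* **Ties** resolve to the lexicographically smallest (uᵢ, vᵢ), enforced
  by sorted iteration order and strict-improvement comparisons.

Scoring inside the DP is incremental: per candidate base alignment and
time point we precompute component labels of the induced image, its
articulation points, and for every gap node the set of components its
neighbours touch.  Removing a non-articulation node keeps its component
whole (split count 1); only articulation-node removals trigger a local
component recount.  Evaluating one candidate swap then costs O(degree)
instead of a full component recount, and the returned breakdown is always
recomputed from scratch as a guard (tests compare both paths).

## Synthetic data

The generator emulates the benchmark conditions the method is designed
for:

* **Target t₀**: Barabási–Albert preferential attachment with attachment
  count mean_degree/2 (default mean degree 4), giving a connected
  scale-free graph with attach·(n − attach) edges.
* **Planted query**: a connected induced subnetwork grown by uniform
  frontier sampling (default 50 nodes).  Its nodes/edges are marked
  *cold* in the target, everything else *hot*; query nodes keep their
  target labels, so the ground truth is label identity.
* **Evolution**: per step, a cold edge is removed with probability ε^c
  and replaced between two random cold nodes; a hot edge with probability
  ε^h = (ε − ε^c·γ)/(1 − γ) (γ = realized cold-edge fraction) and replaced
  between two random nodes with at least one hot.  Replacements avoid
  self-loops, existing edges, *and* edges removed in the same step — the
  last clause is a deliberate design choice: without it a few percent of
  replacements at high ε silently re-create just-removed edges and the
  realized turnover rate falls measurably below ε.  Edge counts are
  conserved (a removal with no free replacement slot is undone and
  logged; at default densities this does not occur in practice).
  Infeasible parameter combinations (ε^h ∉ [0, 1]) are rejected before
  any generation.
* **Query evolution** is independent of the target's (separate RNG
  streams), all query edges being cold; connectivity at every time point
  is enforced by re-sampling a replacement up to 100 times and, as a last
  resort, rejecting the removal.  This slightly depresses the query's
  realized turnover below ε^c when the query is tree-like; the target's
  rates are unaffected.
* **Homology**: log-normal with log-space location 2μ for a planted pair
  (query node vs. its own cold origin) and μ otherwise, scale σ both ways
  (defaults μ = 2, σ = 0.25), fixed across time points.  "Location 2μ"
  was chosen over "arithmetic mean 2μ"; under either consistent reading
  the planted and background distributions barely overlap at σ = 0.25
  (see limitations).
* All randomness flows from one master seed through named
  `SeedSequence`-spawned sub-streams (target t₀, planting, each network's
  evolution, homology), so every stage is individually reproducible.

What the simulator does *not* emulate: node gain/loss, duplication or
divergence models, weighted or directed interactions, correlated
query/target evolution, or the measurement noise of real expression and
interaction data.  Passing tests therefore demonstrate correctness of the
algorithmic machinery under the stated generative model, not performance
on any real dataset.

## Evaluation measures

* **Recovered region**: percentage of query nodes mapped to their planted
  origin.
* **ICS / EC**: per-time conserved-edge fraction with denominator the
  induced image's edges (ICS) or the query's edges (EC), summed over time
  points (each total in [0, t]); a 0/0 time point contributes 0.  Logs
  also report per-time means for cross-t comparability.
* **z-score**: the alignment score against ≥ 2 (default 1000) uniformly
  random injective maps (random target subset + random bijection),
  scored with the identical objective; a zero-variance null is an error.
  The null's RNG stream is independent of the simulator's.
* **impose_static_alignment** evaluates one-alignment-per-time-point
  outputs (from static aligners) across all time points and averages the
  totals — the standard protocol for comparing static aligners on
  temporal data.

## Real-data preprocessing

`build_condition_networks` thresholds a static interaction network by
per-condition expression (an edge survives a condition iff both endpoints
are expressed at or above the cut-off — monotone in the cut-off), and
`interleave_time_points` carves non-overlapping interleaved condition
series (e.g. stride 5, take 7, offsets 0..4) out of an ordered series.
No external dataset is bundled; these are generic operations on
user-supplied TSVs.

## Problem sizes used in tests and the acceptance script

End-to-end checks run at target sizes 100–250 with a 50-node query and
2–5 time points, 10 seeds per condition; DP optimality is verified
exhaustively on instances small enough to enumerate (|V¹| ≤ 4, |V²| ≤ 7,
k ≤ 2) and exactly at k = 1; propagation is verified against dense linear
solves up to mn = 400 pairs.  These sizes were chosen so the full suite
re-runs in minutes while still exercising every code path at realistic
density.

## Known limitations

* The swap DP is a heuristic: it is sandwiched between the initial score
  and the exhaustive optimum, and exact only at k = 1.  No ILP/exact
  solver is provided for the NP-hard selection problem.
* With the default homology parameters (μ = 2, σ = 0.25) the planted and
  background score distributions are nearly separable, so the initial
  matching alone already recovers ≈ 97–100 % of the planted region; the
  refinement phase is monotone in the *score*, and because the target's
  cold region evolves independently of the query, the score-optimal
  connected image can deviate slightly from the planted truth.  Under
  these conditions refinement mainly buys connectivity and significance,
  not additional recovery.
* Alignment requires equal time-point counts and a one-to-one global
  mapping; no local or many-to-many alignment.
* `interleave_time_points` assumes the condition series is already
  ordered and uniformly usable; irregular-gap filtering (e.g. dropping
  conditions separated by large gaps) is left to the caller.
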