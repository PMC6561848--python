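"""Co-evolving temporal network simulator with a planted alignment.

The generator emulates a pair of temporal protein-interaction-like
networks whose ground-truth correspondence is known:

* the target starts as a Barabasi-Albert scale-free graph (attachment
  count = mean_degree / 2, so the realised mean degree approaches the
  requested value);
* the query is a uniformly grown connected induced subnetwork of the
  target's first snapshot; its nodes and edges are marked *cold* in the
  target, everything else *hot*;
* both networks then evolve independently by edge turnover: a cold edge is
  removed with probability ``eps_c`` and replaced by a fresh edge between
  two random cold nodes, a hot edge with probability ``eps_h`` and replaced
  between two random nodes of which at least one is hot.  With ``gamma``
  the cold-edge fraction, ``eps_h = (eps - eps_c * gamma) / (1 - gamma)``
  so the overall turnover rate is ``eps``;
* homology scores are log-normal, with log-space location ``2 * mu`` for a
  planted pair (query node against its own cold origin) and ``mu``
  otherwise, scale ``sigma`` in both cases, fixed across time points.

Query nodes keep their origin target labels, so the planted truth map is
label identity; the query is kept connected at every time point by
re-sampling replacement edges (and, as a last resort, keeping the edge
that would disconnect it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .netio import Edge, TemporalNetwork, canonical_edge

logger = logging.getLogger(__name__)

DEFAULT_MEAN_DEGREE = 4.0
DEFAULT_QUERY_SIZE = 50
DEFAULT_MU = 2.0
DEFAULT_SIGMA = 0.25


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of one simulated instance.

    ``epsilon`` is the overall per-step edge turnover rate; ``epsilon_c``
    the turnover rate of the planted (cold) region, with
    ``0 <= epsilon_c <= epsilon <= 1``.  Defaults mirror the study
    conditions: mean degree 4, 50-node query, log-normal homology with
    ``mu = 2``, ``sigma = 0.25``.
    """

    n_target: int
    t: int
    epsilon: float
    epsilon_c: float
    q_size: int = DEFAULT_QUERY_SIZE
    mean_degree: float = DEFAULT_MEAN_DEGREE
    mu: float = DEFAULT_MU
    sigma: float = DEFAULT_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon_c <= self.epsilon <= 1.0):
            raise ValueError("need 0 <= epsilon_c <= epsilon <= 1")
        if not 1 <= self.q_size <= self.n_target:
            raise ValueError("need 1 <= q_size <= n_target")
        if self.t < 1:
            raise ValueError("need t >= 1")
        if self.mu <= 0 or self.sigma <= 0:
            raise ValueError("mu and sigma must be positive")


@dataclass(frozen=True)
class SyntheticInstance:
    """A generated query/target pair with its planted ground truth."""

    params: SyntheticParams
    query: TemporalNetwork
    target: TemporalNetwork
    cold_nodes: frozenset
    cold_edges: frozenset  # cold edges of the target's first snapshot
    gamma: float
    truth: dict  # query node -> origin target node (label identity)
    homology: np.ndarray = field(repr=False)


def generate_target_t0(n: int, mean_degree: float, seed) -> nx.Graph:
    """Scale-free first snapshot via Barabasi-Albert preferential attachment.

    The attachment count is ``mean_degree / 2`` (each new node brings that
    many edges), giving ``attach * (n - attach)`` edges in total and a
    realised mean degree that approaches ``mean_degree`` for large n.
    Node labels are strings ``v000..``; the graph is connected.
    """
    attach = int(round(mean_degree / 2))
    if attach < 1 or n <= attach:
        raise ValueError(f"infeasible BA parameters: n={n}, mean_degree={mean_degree}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g = nx.barabasi_albert_graph(n, attach, seed=rng)
    width = len(str(n - 1))
    return nx.relabel_nodes(g, {i: f"v{i:0{width}d}" for i in g.nodes})


def plant_query(target_t0: nx.Graph, q_size: int, seed):
    """Grow a uniform random connected induced subnetwork of the target.

    Returns ``(query_t0, cold_nodes, cold_edges, truth)`` where the query
    keeps the target labels (truth is label identity on the cold nodes).
    """
    if q_size > target_t0.number_of_nodes():
        raise ValueError("q_size exceeds the target size")
    if not nx.is_connected(target_t0):
        raise ValueError("target first snapshot must be connected")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    nodes = sorted(target_t0.nodes)
    start = nodes[rng.integers(len(nodes))]
    chosen = {start}
    frontier = sorted(target_t0.neighbors(start))
    while len(chosen) < q_size:
        pick = frontier[rng.integers(len(frontier))]
        chosen.add(pick)
        frontier = sorted(
            {w for u in chosen for w in target_t0.neighbors(u)} - chosen
        )
    query_t0 = target_t0.subgraph(chosen).copy()
    cold_nodes = frozenset(chosen)
    cold_edges = frozenset(canonical_edge(u, v) for u, v in query_t0.edges)
    truth = {u: u for u in chosen}
    return query_t0, cold_nodes, cold_edges, truth


def hot_rate(epsilon: float, epsilon_c: float, gamma: float) -> float:
    """Turnover rate of hot edges, ``(eps - eps_c * gamma) / (1 - gamma)``.

    Chosen so the expected overall removed-edge fraction per step is
    exactly ``epsilon``; out-of-range results mean the requested (eps,
    eps_c, gamma) combination is infeasible.
    """
    if not (0.0 <= epsilon_c <= epsilon <= 1.0):
        raise ValueError("need 0 <= epsilon_c <= epsilon <= 1")
    if gamma >= 1.0:
        raise ValueError("gamma must be < 1 (some hot edges must exist)")
    eh = (epsilon - epsilon_c * gamma) / (1.0 - gamma)
    if not 0.0 <= eh <= 1.0:
        raise ValueError(
            f"hot rate {eh:.4g} outside [0, 1] for epsilon={epsilon}, "
            f"epsilon_c={epsilon_c}, gamma={gamma}: lower epsilon or gamma"
        )
    return eh


def evolve_snapshot(
    edges: frozenset[Edge],
    cold_marks: frozenset[Edge],
    cold_nodes: frozenset,
    all_nodes,
    eps_c: float,
    eps_h: float,
    rng: np.random.Generator,
    max_retries: int = 100,
):
    """One step of cold/hot edge turnover; edge count is conserved.

    A removed cold edge is replaced by a new edge between two random cold
    nodes; a removed hot edge by one between two random nodes with at least
    one hot endpoint.  Replacements are re-sampled to avoid self-loops and
    duplicates; if no slot is found in ``max_retries`` draws the
    replacement is skipped with a warning (the removal is then undone so
    the count stays conserved).  Returns ``(new_edges, new_cold_marks)``.
    """
    if not (0.0 <= eps_c <= 1.0 and 0.0 <= eps_h <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    all_nodes = sorted(all_nodes)
    cold_list = sorted(cold_nodes)
    hot_list = sorted(set(all_nodes) - cold_nodes)

    removed = []
    for e in sorted(edges):
        is_cold = e in cold_marks
        if rng.random() < (eps_c if is_cold else eps_h):
            removed.append((e, is_cold))

    current = set(edges) - {e for e, _ in removed}
    marks = set(cold_marks) - {e for e, _ in removed}
    # replacements avoid self-loops, existing edges, and edges removed in
    # this same step, so each decided removal really turns the edge over
    for e, is_cold in removed:
        replacement = None
        for _ in range(max_retries):
            if is_cold:
                if len(cold_list) < 2:
                    break
                u, v = rng.choice(len(cold_list), size=2, replace=False)
                cand = canonical_edge(cold_list[u], cold_list[v])
            else:
                if not hot_list:
                    break
                a = hot_list[rng.integers(len(hot_list))]
                b = all_nodes[rng.integers(len(all_nodes))]
                if a == b:
                    continue
                cand = canonical_edge(a, b)
            if cand not in current and cand not in edges:
                replacement = cand
                break
        if replacement is None:
            logger.warning("no free slot for a %s replacement edge; keeping %s",
                           "cold" if is_cold else "hot", e)
            current.add(e)
            if is_cold:
                marks.add(e)
            continue
        current.add(replacement)
        if is_cold:
            marks.add(replacement)
    return frozenset(current), frozenset(marks)


def _evolve_query(
    edges: frozenset[Edge],
    nodes,
    eps_c: float,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> frozenset[Edge]:
    """Query turnover: all edges cold, connectivity preserved.

    Replacement edges connect two random query nodes; a draw that would
    leave the query disconnected is re-sampled, and if no connected
    replacement exists the offending removal is rejected.
    """
    node_list = sorted(nodes)
    current = set(edges)
    for e in sorted(edges):
        if rng.random() >= eps_c:
            continue
        current.discard(e)
        replacement = None
        for _ in range(max_retries):
            if len(node_list) < 2:
                break
            u, v = rng.choice(len(node_list), size=2, replace=False)
            cand = canonical_edge(node_list[u], node_list[v])
            if cand in current or cand in edges:
                continue
            current.add(cand)
            if _connected(node_list, current):
                replacement = cand
                break
            current.discard(cand)
        if replacement is None:
            current.add(e)  # keep the edge rather than disconnect the query
    return frozenset(current)


def _connected(nodes, edges) -> bool:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return nx.is_connected(g)


def synth_homology(
    truth: dict,
    query_nodes,
    target_nodes,
    cold_nodes,
    mu: float,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Log-normal homology favouring planted pairs.

    ``H[u, v]`` has log-space location ``2 * mu`` when v is a cold node and
    the planted origin of u, and ``mu`` otherwise; scale ``sigma`` both
    ways.  Scores are fixed across time points.
    """
    q = list(query_nodes)
    t = list(target_nodes)
    h = rng.lognormal(mean=mu, sigma=sigma, size=(len(q), len(t)))
    planted = rng.lognormal(mean=2.0 * mu, sigma=sigma, size=len(q))
    tidx = {v: j for j, v in enumerate(t)}
    for i, u in enumerate(q):
        v = truth.get(u)
        if v is not None and v in cold_nodes and v in tidx:
            h[i, tidx[v]] = planted[i]
    return h


def generate_instance(params: SyntheticParams) -> SyntheticInstance:
    """Generate a full co-evolving pair with planted truth.

    Named RNG sub-streams (target seed, query planting, per-network
    evolution, homology) are derived from the master seed so each stage is
    individually reproducible.
    """
    ss = np.random.SeedSequence(params.seed)
    seeds = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("target_t0", "plant", "target_evo", "query_evo", "homology"),
            ss.spawn(5),
        )
    }
    target_t0 = generate_target_t0(params.n_target, params.mean_degree, seeds["target_t0"])
    query_t0, cold_nodes, cold_edges, truth = plant_query(
        target_t0, params.q_size, seeds["plant"]
    )
    target_edges0 = frozenset(canonical_edge(u, v) for u, v in target_t0.edges)
    gamma = len(cold_edges) / len(target_edges0)
    eps_h = hot_rate(params.epsilon, params.epsilon_c, gamma)

    target_nodes = tuple(sorted(target_t0.nodes))
    query_nodes = tuple(sorted(query_t0.nodes))

    target_snaps = [target_edges0]
    marks = cold_edges
    for _ in range(1, params.t):
        nxt, marks = evolve_snapshot(
            target_snaps[-1], marks, cold_nodes, target_nodes,
            params.epsilon_c, eps_h, seeds["target_evo"],
        )
        target_snaps.append(nxt)

    query_edges0 = frozenset(canonical_edge(u, v) for u, v in query_t0.edges)
    query_snaps = [query_edges0]
    for _ in range(1, params.t):
        query_snaps.append(
            _evolve_query(query_snaps[-1], query_nodes, params.epsilon_c,
                          seeds["query_evo"])
        )

    target = TemporalNetwork(nodes=target_nodes, snapshots=tuple(target_snaps))
    query = TemporalNetwork(nodes=query_nodes, snapshots=tuple(query_snaps))
    homology = synth_homology(
        truth, query_nodes, target_nodes, cold_nodes,
        params.mu, params.sigma, seeds["homology"],
    )
    return SyntheticInstance(
        params=params,
        query=query,
        target=target,
        cold_nodes=cold_nodes,
        cold_edges=cold_edges,
        gamma=gamma,
        truth=truth,
        homology=homology,
    )
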