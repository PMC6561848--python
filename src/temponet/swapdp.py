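"""Refinement phase: select up to k (aligned-node, gap-node) swaps.

The initial maximum-weight matching ignores the connectivity penalty, so the
image of the alignment in the target network is usually fragmented.  A
*swap* replaces one aligned target node with a gap node, leaving the rest
of the mapping intact.  Choosing the set of at most k swaps that minimises
the number of connected components across all time points is NP-hard (it
encodes Maximum Coverage; see :func:`mcp_reduction`), so the selection is
done with an iterative dynamic program over *branches*: for every aligned
target node ``u_i``, ``solution(r, u_i)`` is the best known set of r swaps
that contains a swap of ``u_i``.  Iteration 1 scans all single swaps;
iteration r extends every ``solution(r-1, u_j)`` by one feasible pair
``(u_i, v_i)`` (``u_i`` not yet swapped in the base set, ``v_i`` not yet
used) and keeps the extension only if it does not degrade the branch, so
the best recorded score is non-decreasing in r.  The answer is the best
branch of the final iteration, never worse than the unrefined alignment.

Scoring inside the DP is incremental: for each candidate base alignment the
per-time component labels, articulation points and gap-node component
adjacencies are precomputed, so evaluating one more swap costs
O(degree) instead of a full component recount.  A from-scratch
:func:`~temponet.align.alignment_score` recomputation backs every returned
score (and is what the tests compare against).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .align import Alignment, ScoreBreakdown, alignment_score, induced_subnetwork, ncc
from .netio import TemporalNetwork
from .simscore import ScoreSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SwapSet:
    """An ordered set of (aligned target node, gap node) swap pairs."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        us = [u for u, _ in self.pairs]
        vs = [v for _, v in self.pairs]
        if len(set(us)) != len(us):
            raise ValueError("swapped-out nodes must be distinct")
        if len(set(vs)) != len(vs):
            raise ValueError("swapped-in nodes must be distinct")
        if set(us) & set(vs):
            raise ValueError("a node cannot be both swapped out and swapped in")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class SwapResult:
    """Outcome of the swap-selection DP."""

    swaps: SwapSet
    alignment: Alignment
    breakdown: ScoreBreakdown
    initial_score: float
    iteration_best: tuple[float, ...]  # best branch score after each DP iteration


def apply_swap(psi: Alignment, u_old: str, v_new: str) -> Alignment:
    """Swap aligned target node ``u_old`` with gap node ``v_new``."""
    if u_old not in psi.image:
        raise ValueError(f"{u_old!r} is not an aligned target node")
    if v_new not in psi.gap_nodes:
        raise ValueError(f"{v_new!r} is not a gap node")
    mapping = psi.mapping
    q = next(u for u, v in mapping.items() if v == u_old)
    mapping[q] = v_new
    return Alignment.from_mapping(mapping, psi.target_nodes)


def apply_swaps(psi: Alignment, swaps: SwapSet) -> Alignment:
    """Apply all swaps of a set; disjointness makes the order irrelevant."""
    out = psi
    for u, v in swaps.pairs:
        out = apply_swap(out, u, v)
    return out


def best_single_swap(
    net1: TemporalNetwork,
    net2: TemporalNetwork,
    scores: ScoreSet,
    psi: Alignment,
    u_i: str,
    delta: float,
) -> tuple[SwapSet, float]:
    """Exhaustive best swap of aligned node ``u_i`` with any gap node.

    Ties resolve to the lexicographically smallest gap-node label.
    """
    gaps = sorted(psi.gap_nodes)
    if not gaps:
        raise ValueError("no gap nodes: no swap is possible")
    if u_i not in psi.image:
        raise ValueError(f"{u_i!r} is not an aligned target node")
    best_v, best_score = None, -np.inf
    for v in gaps:
        score = alignment_score(net1, net2, scores, apply_swap(psi, u_i, v), delta).total
        if score > best_score:
            best_v, best_score = v, score
    return SwapSet(pairs=((u_i, best_v),)), best_score


def default_k(net2: TemporalNetwork, psi0: Alignment) -> int:
    """Default swap budget: worst-time-point component count minus one.

    Floored at 1 and capped at the number of gap nodes.
    """
    image = psi0.image
    worst = max(ncc(induced_subnetwork(net2.graph(i), image)) for i in range(net2.t))
    return max(1, min(worst - 1, len(psi0.gap_nodes)))


@dataclass
class _Branch:
    pairs: tuple[tuple[str, str], ...]
    score: float
    used_u: frozenset
    used_v: frozenset


class _IncrementalScorer:
    """Per-base precomputation for O(degree) evaluation of one extra swap.

    Given the image of a base alignment, precomputes at every time point the
    component labels of the induced target subnetwork, its articulation
    points, and for every candidate gap node the number of distinct
    components its neighbours touch.  ``delta_ncc(u_old)`` then returns, for
    all candidates v at once, the total change in component count (summed
    over time) of swapping ``u_old`` out and v in.
    """

    def __init__(self, nbrs_t, image, cand, cand_pos):
        self.nbrs_t = nbrs_t
        self.image = image
        self.cand = cand
        self.cand_pos = cand_pos
        self.t = len(nbrs_t)
        self.labels_t, self.members_t, self.art_t = [], [], []
        self.vnbrs_t, self.comp_vpos_t = [], []
        nadj0_sum = np.zeros(len(cand))
        self.nadj0_t = []
        for nbrs in nbrs_t:
            labels, members = _components(image, nbrs)
            g = nx.Graph()
            g.add_nodes_from(image)
            g.add_edges_from(
                (u, w) for u in image for w in nbrs.get(u, ()) if w in image and u < w
            )
            art = set(nx.articulation_points(g))
            vnbrs = {v: [w for w in nbrs.get(v, ()) if w in image] for v in cand}
            nadj0 = np.zeros(len(cand))
            comp_vpos: dict[int, list[int]] = {}
            for p, v in enumerate(cand):
                touched = {labels[w] for w in vnbrs[v]}
                nadj0[p] = len(touched)
                for lab in touched:
                    comp_vpos.setdefault(lab, []).append(p)
            self.labels_t.append(labels)
            self.members_t.append(members)
            self.art_t.append(art)
            self.vnbrs_t.append(vnbrs)
            self.comp_vpos_t.append(comp_vpos)
            self.nadj0_t.append(nadj0)
            nadj0_sum += nadj0
        self.nadj0_sum = nadj0_sum

    def delta_ncc(self, u_old) -> np.ndarray:
        """Summed-over-time NCC change for swapping u_old out, each v in."""
        split_total = 0
        corr = np.zeros(len(self.cand))
        for i in range(self.t):
            labels = self.labels_t[i]
            lab = labels[u_old]
            members = self.members_t[i][lab]
            vnbrs = self.vnbrs_t[i]
            nbrs = self.nbrs_t[i]
            if len(members) == 1:
                # u_old was an isolated component; v loses it as a neighbour comp
                for p in self.comp_vpos_t[i].get(lab, ()):
                    corr[p] -= 1.0
            elif u_old not in self.art_t[i]:
                split_total += 1
                # removal keeps the component whole; only v adjacent solely
                # through u_old loses a neighbour component
                for p in self.comp_vpos_t[i].get(lab, ()):
                    v = self.cand[p]
                    if not any(w != u_old and labels.get(w) == lab for w in vnbrs[v]):
                        corr[p] -= 1.0
            else:
                rest = [w for w in members if w != u_old]
                sub_labels, sub_members = _components(rest, nbrs)
                split_total += len(sub_members)
                for p in self.comp_vpos_t[i].get(lab, ()):
                    v = self.cand[p]
                    touched = set()
                    for w in vnbrs[v]:
                        if w == u_old:
                            continue
                        if labels.get(w) == lab:
                            touched.add(("s", sub_labels[w]))
                        else:
                            touched.add(("o", labels[w]))
                    corr[p] += len(touched) - self.nadj0_t[i][p]
        return split_total - (self.nadj0_sum + corr)


def _components(nodes, nbrs):
    """Connected components of the subgraph induced on ``nodes``."""
    node_set = set(nodes)
    labels: dict[str, int] = {}
    members: dict[int, list] = {}
    comp = 0
    for s in nodes:
        if s in labels:
            continue
        labels[s] = comp
        members[comp] = [s]
        stack = [s]
        while stack:
            x = stack.pop()
            for y in nbrs.get(x, ()):
                if y in node_set and y not in labels:
                    labels[y] = comp
                    members[comp].append(y)
                    stack.append(y)
        comp += 1
    return labels, members


def select_swaps(
    net1: TemporalNetwork,
    net2: TemporalNetwork,
    scores: ScoreSet,
    psi0: Alignment,
    k: int,
    delta: float,
) -> SwapResult:
    """Select up to ``k`` swaps with the branch-per-aligned-node DP.

    Returns the chosen swap set, the refined alignment and its score
    breakdown.  With ``delta`` at least every per-time pair score the best
    recorded score is non-decreasing over iterations and the final score
    never falls below the initial one; if at some iteration no extension
    helps a branch, the branch carries its smaller set forward.
    """
    gap0 = sorted(psi0.gap_nodes)
    if not 1 <= k <= len(gap0):
        raise ValueError(f"k must be in [1, |F|] = [1, {len(gap0)}], got {k}")
    per_time_max = max(float(s.max()) for s in scores.per_time)
    if delta < per_time_max:
        logger.warning(
            "delta=%.6g is below the largest per-time pair score %.6g; "
            "monotone improvement is not guaranteed",
            delta, per_time_max,
        )

    initial = alignment_score(net1, net2, scores, psi0, delta).total
    image0 = sorted(psi0.image)
    q_of = {v: u for u, v in psi0.psi}
    agg = scores.aggregate
    cand_cols = np.array([scores.target_index(v) for v in gap0])
    cand_pos = {v: p for p, v in enumerate(gap0)}
    nbrs_t = [_neighbor_map(net2, i) for i in range(net2.t)]

    def extensions(base: _Branch, best: dict[str, _Branch]) -> None:
        """Score all feasible one-swap extensions of ``base`` into ``best``."""
        base_image = (set(image0) - base.used_u) | base.used_v
        scorer = _IncrementalScorer(nbrs_t, sorted(base_image), gap0, cand_pos)
        blocked = np.array([v in base.used_v for v in gap0])
        for u_old in image0:
            if u_old in base.used_u:
                continue
            q_row = scores.query_index(q_of[u_old])
            sim = agg[q_row, cand_cols] - agg[q_row, scores.target_index(u_old)]
            gain = sim - delta * scorer.delta_ncc(u_old)
            gain[blocked] = -np.inf
            p = int(np.argmax(gain))  # first max => smallest gap label
            if not np.isfinite(gain[p]):
                continue  # every gap node already consumed by this base
            score = base.score + float(gain[p])
            cur = best.get(u_old)
            if cur is None or score > cur.score:
                v_new = gap0[p]
                best[u_old] = _Branch(
                    pairs=base.pairs + ((u_old, v_new),),
                    score=score,
                    used_u=base.used_u | {u_old},
                    used_v=base.used_v | {v_new},
                )

    root = _Branch(pairs=(), score=initial, used_u=frozenset(), used_v=frozenset())
    branches: dict[str, _Branch] = {}
    extensions(root, branches)
    iteration_best = [max(b.score for b in branches.values())]

    for _ in range(2, k + 1):
        nxt: dict[str, _Branch] = {}
        for key in image0:
            if key in branches:
                extensions(branches[key], nxt)
        # a branch whose best extension degrades it keeps its smaller set
        for key, prev in branches.items():
            cur = nxt.get(key)
            if cur is None or cur.score < prev.score:
                nxt[key] = prev
        branches = nxt
        iteration_best.append(max(b.score for b in branches.values()))

    final = root
    for key in image0:
        b = branches.get(key)
        if b is not None and b.score > final.score:
            final = b
    if len(final.pairs) < k:
        logger.info(
            "returned %d swaps out of a budget of %d: no further "
            "non-degrading extension was available", len(final.pairs), k,
        )

    swaps = SwapSet(pairs=final.pairs)
    psi = apply_swaps(psi0, swaps)
    breakdown = alignment_score(net1, net2, scores, psi, delta)
    return SwapResult(
        swaps=swaps,
        alignment=psi,
        breakdown=breakdown,
        initial_score=initial,
        iteration_best=tuple(iteration_best),
    )


def _neighbor_map(net: TemporalNetwork, i: int) -> dict:
    nbrs: dict[str, set] = {u: set() for u in net.nodes}
    for u, v in net.snapshots[i]:
        nbrs[u].add(v)
        nbrs[v].add(u)
    return nbrs


def mcp_reduction(sets, k: int):
    """Encode a Maximum Coverage instance as a single-snapshot swap problem.

    For sets ``S_1..S_m`` over a universe of n elements, the target network
    has an element node ``a_j`` per element, and per set a swappable-out
    node ``b_i`` and a gap node ``f_i``; ``f_i`` is adjacent to the element
    nodes of ``S_i`` and to every other ``f_j``.  The aligned set (all a and
    b nodes) induces an edgeless subnetwork, so it starts at n + m
    components; swapping in k gap nodes ``f_i`` (for ``b`` nodes) covering
    tau elements leaves beta = (m + n - k + 1) - tau components, making
    component minimisation equivalent to coverage maximisation.

    Returns ``(graph, aligned_nodes, gap_nodes)``.
    """
    sets = [set(s) for s in sets]
    if not sets or any(not s for s in sets):
        raise ValueError("need a nonempty collection of nonempty sets")
    m = len(sets)
    if not 1 <= k <= m:
        raise ValueError(f"k must be in [1, {m}]")
    universe = sorted(set().union(*sets))
    elem_node = {x: f"a{j}" for j, x in enumerate(universe)}
    g = nx.Graph()
    g.add_nodes_from(elem_node.values())
    g.add_nodes_from(f"b{i}" for i in range(m))
    g.add_nodes_from(f"f{i}" for i in range(m))
    for i, s in enumerate(sets):
        for x in s:
            g.add_edge(f"f{i}", elem_node[x])
    for i, j in itertools.combinations(range(m), 2):
        g.add_edge(f"f{i}", f"f{j}")
    aligned = frozenset(elem_node.values()) | frozenset(f"b{i}" for i in range(m))
    gaps = frozenset(f"f{i}" for i in range(m))
    return g, aligned, gaps
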