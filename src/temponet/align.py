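"""Alignment representation, component-penalty scoring, and the initial match.

An alignment maps every query node injectively to a target node; target
nodes left unmapped are *gap nodes*.  The score of an alignment at one time
point is the summed pair similarity of the mapped nodes minus a penalty of
``delta`` per edge insertion that would be needed to connect the induced
subnetwork of the image (joining c components takes c - 1 edges):

    score_i(psi) = sum_u S_i(u, psi(u)) - delta * (NCC_i(image) - 1)

and the temporal score is the sum over all time points.  When delta is at
least every per-time pair similarity (guaranteed by the default, the max
aggregate score), merging components can never be outweighed by a loss of
pair similarity, which is what makes the swap refinement monotone.

The initial alignment is the maximum-weight bipartite matching of query to
target nodes under the aggregate scores, computed with the Hungarian
algorithm (``scipy.optimize.linear_sum_assignment``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .netio import TemporalNetwork
from .simscore import ScoreSet


@dataclass(frozen=True)
class Alignment:
    """Injective map ``psi`` from query nodes to target nodes.

    ``target_nodes`` fixes the universe from which the gap set
    ``F = V2 - image(psi)`` is derived.
    """

    psi: tuple[tuple[str, str], ...]  # (query, target) pairs, query-sorted
    target_nodes: tuple[str, ...]

    @classmethod
    def from_mapping(cls, mapping: dict, target_nodes) -> "Alignment":
        return cls(
            psi=tuple(sorted(mapping.items())),
            target_nodes=tuple(target_nodes),
        )

    def __post_init__(self) -> None:
        images = [v for _, v in self.psi]
        if len(set(images)) != len(images):
            raise ValueError("alignment is not injective")
        queries = [u for u, _ in self.psi]
        if len(set(queries)) != len(queries):
            raise ValueError("duplicate query node in alignment")
        tset = set(self.target_nodes)
        missing = [v for v in images if v not in tset]
        if missing:
            raise ValueError(f"aligned target nodes not in target set: {missing[:3]}")

    @property
    def mapping(self) -> dict:
        return dict(self.psi)

    @property
    def image(self) -> frozenset:
        """Aligned target nodes, Psi(V1)."""
        return frozenset(v for _, v in self.psi)

    @property
    def gap_nodes(self) -> frozenset:
        """Target nodes outside the image, F = V2 - Psi(V1)."""
        return frozenset(self.target_nodes) - self.image

    def __len__(self) -> int:
        return len(self.psi)


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-time similarity, component counts and penalties of one alignment."""

    per_time_similarity: tuple[float, ...]
    per_time_ncc: tuple[int, ...]
    delta: float
    per_time_score: tuple[float, ...] = field(default=())
    total: float = field(default=0.0)

    @classmethod
    def build(cls, sims, nccs, delta) -> "ScoreBreakdown":
        per_score = tuple(s - delta * (c - 1) for s, c in zip(sims, nccs))
        return cls(
            per_time_similarity=tuple(sims),
            per_time_ncc=tuple(nccs),
            delta=delta,
            per_time_score=per_score,
            total=float(sum(per_score)),
        )


def induced_subnetwork(g: nx.Graph, nodes) -> nx.Graph:
    """Induced subgraph on ``nodes`` (all edges with both endpoints inside)."""
    nodes = set(nodes)
    unknown = nodes - set(g.nodes)
    if unknown:
        raise KeyError(f"nodes not in graph: {sorted(unknown)[:3]}")
    return g.subgraph(nodes).copy()


def ncc(g: nx.Graph) -> int:
    """Number of (maximal) connected components; isolated nodes count one each."""
    return nx.number_connected_components(g)


def alignment_score(
    net1: TemporalNetwork,
    net2: TemporalNetwork,
    scores: ScoreSet,
    psi: Alignment,
    delta: float,
) -> ScoreBreakdown:
    """Evaluate the temporal alignment score with component penalty delta."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if net1.t != net2.t:
        raise ValueError("query and target must share the number of time points")
    if len(psi) != net1.n_nodes:
        raise ValueError("alignment must map every query node")
    if len(psi) == 0:
        raise ValueError("empty query network cannot be scored")
    q_idx = np.array([scores.query_index(u) for u, _ in psi.psi])
    t_idx = np.array([scores.target_index(v) for _, v in psi.psi])
    image = psi.image
    sims, nccs = [], []
    for i in range(net1.t):
        sims.append(float(scores.per_time[i][q_idx, t_idx].sum()))
        nccs.append(ncc(induced_subnetwork(net2.graph(i), image)))
    return ScoreBreakdown.build(sims, nccs, delta)


def default_delta(scores: ScoreSet) -> float:
    """Paper-default edge-insertion penalty: the maximum aggregate score.

    Because per-time scores are non-negative and sum to the aggregate, this
    dominates every S_i(u, v), which is the precondition for the swap
    refinement to be monotone.
    """
    if scores.aggregate.size == 0:
        raise ValueError("empty score matrix")
    return float(scores.aggregate.max())


def initial_alignment(scores: ScoreSet) -> Alignment:
    """Maximum-weight injective assignment of query to target nodes.

    The complete bipartite graph is weighted by the aggregate scores
    S(u, v); absent pairs weigh 0.  Rows and columns are processed in
    sorted-label order so ties resolve deterministically.
    """
    m, n = scores.aggregate.shape
    if m > n:
        raise ValueError(
            f"query must be the smaller network (|V1|={m} > |V2|={n})"
        )
    rows, cols = linear_sum_assignment(scores.aggregate, maximize=True)
    mapping = {
        scores.query_nodes[r]: scores.target_nodes[c] for r, c in zip(rows, cols)
    }
    return Alignment.from_mapping(mapping, scores.target_nodes)


def read_alignment(path, target_nodes) -> Alignment:
    """Read a ``query<TAB>target`` TSV written by :func:`write_alignment`."""
    mapping = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            mapping[parts[0]] = parts[1]
    return Alignment.from_mapping(mapping, target_nodes)


def write_alignment(path, psi: Alignment, header_meta: dict | None = None) -> None:
    """Write an alignment as a TSV, with metadata in comment lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (header_meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        for u, v in psi.psi:
            fh.write(f"{u}\t{v}\n")


def write_score_report(path, breakdown: ScoreBreakdown) -> None:
    """Per-time-point score report TSV plus a total line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#time\tsimilarity\tncc\tscore\n")
        for i, (s, c, sc) in enumerate(
            zip(
                breakdown.per_time_similarity,
                breakdown.per_time_ncc,
                breakdown.per_time_score,
            )
        ):
            fh.write(f"{i}\t{s:.12g}\t{c}\t{sc:.12g}\n")
        fh.write(f"#total\t{breakdown.total:.12g}\n")
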