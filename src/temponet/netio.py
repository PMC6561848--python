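"""Temporal network data model, TSV I/O and condition-network construction.

A temporal network is a sequence of undirected snapshots ``G_1..G_t`` over a
single, fixed node set: nodes persist through time, only edges change.  The
canonical on-disk form is a long-format TSV with one edge per line
(``time<TAB>u<TAB>v``), ``#``-prefixed comment lines, and an optional
``#nodes: a,b,c`` declaration for nodes that are isolated at every time
point.  Time indices found in a file are densified to ``0..t-1`` preserving
their order.

This module also provides the two preprocessing operations used to carve
temporal networks out of expression data: thresholding a static interaction
network by per-condition expression (an edge survives a condition only if
both endpoints are expressed at or above the cut-off) and selecting
interleaved time points from an ordered condition series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


class TemporalNetworkError(ValueError):
    """Raised for malformed temporal-network files or invalid structures."""


def canonical_edge(u: str, v: str) -> Edge:
    """Return the undirected edge (u, v) in canonical (sorted) order."""
    if u == v:
        raise TemporalNetworkError(f"self-loop on node {u!r} is not allowed")
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class TemporalNetwork:
    """A sequence of undirected snapshots over a shared node set.

    Parameters
    ----------
    nodes
        Node labels, in a fixed (sorted) order.  The same set applies to
        every snapshot.
    snapshots
        One frozenset of canonical edges per time point.
    """

    nodes: tuple[str, ...]
    snapshots: tuple[frozenset[Edge], ...]

    def __post_init__(self) -> None:
        if len(self.snapshots) < 1:
            raise TemporalNetworkError("a temporal network needs t >= 1 snapshots")
        if len(set(self.nodes)) != len(self.nodes):
            raise TemporalNetworkError("duplicate node labels")
        node_set = set(self.nodes)
        for i, edges in enumerate(self.snapshots):
            for u, v in edges:
                if u == v:
                    raise TemporalNetworkError(f"self-loop on {u!r} in snapshot {i}")
                if u not in node_set or v not in node_set:
                    raise TemporalNetworkError(
                        f"edge ({u!r}, {v!r}) in snapshot {i} uses an undeclared node"
                    )
                if (u, v) != canonical_edge(u, v):
                    raise TemporalNetworkError(
                        f"edge ({u!r}, {v!r}) in snapshot {i} is not in canonical order"
                    )

    @property
    def t(self) -> int:
        """Number of time points."""
        return len(self.snapshots)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def graph(self, i: int) -> nx.Graph:
        """Snapshot ``i`` as a :class:`networkx.Graph` (isolated nodes kept)."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.snapshots[i])
        return g

    @classmethod
    def from_edges(
        cls,
        snapshots: Sequence[Iterable[tuple[str, str]]],
        nodes: Iterable[str] = (),
    ) -> "TemporalNetwork":
        """Build a network from per-snapshot edge iterables.

        The node set is the union of all endpoints plus any explicitly
        declared ``nodes``; labels are sorted for a stable order.
        """
        canon = [frozenset(canonical_edge(u, v) for u, v in es) for es in snapshots]
        all_nodes = set(nodes)
        for es in canon:
            for u, v in es:
                all_nodes.add(u)
                all_nodes.add(v)
        return cls(nodes=tuple(sorted(all_nodes)), snapshots=tuple(canon))


@dataclass(frozen=True)
class ExpressionTable:
    """A genes x conditions expression matrix with labelled axes."""

    genes: tuple[str, ...]
    conditions: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene labels")
        if self.values.shape != (len(self.genes), len(self.conditions)):
            raise ValueError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.conditions)} conditions"
            )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionTable":
        return cls(
            genes=tuple(str(g) for g in frame.index),
            conditions=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(dtype=float),
        )


def read_temporal_network(path, dialect: str = "long") -> TemporalNetwork:
    """Read a temporal network from disk.

    ``dialect="long"`` reads a single long-format TSV with columns
    ``(time, u, v)``; ``dialect="per-snapshot"`` accepts a list of plain
    edge-list files, one per time point in order.  Time values in the long
    format need not start at 0 nor be contiguous; they are densified to
    ``0..t-1`` preserving order of first appearance by sorted value.
    """
    if dialect == "per-snapshot":
        snaps = []
        declared: set[str] = set()
        for p in path:
            edges, nodes = _parse_edge_lines(p)
            snaps.append(edges)
            declared |= nodes
        if not snaps:
            raise TemporalNetworkError("per-snapshot dialect needs at least one file")
        return TemporalNetwork.from_edges(snaps, nodes=declared)
    if dialect != "long":
        raise ValueError(f"unknown dialect {dialect!r}")

    declared = set()
    declared_t: int | None = None
    records: list[tuple[int, str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.lower().startswith("#nodes:"):
                    body = line.split(":", 1)[1]
                    declared |= {tok.strip() for tok in body.split(",") if tok.strip()}
                elif line.lower().startswith("#t:"):
                    declared_t = int(line.split(":", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise TemporalNetworkError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            try:
                ti = int(parts[0])
            except ValueError as exc:
                raise TemporalNetworkError(
                    f"{path}:{lineno}: time index {parts[0]!r} is not an integer"
                ) from exc
            if parts[1] == parts[2]:
                raise TemporalNetworkError(f"{path}:{lineno}: self-loop on {parts[1]!r}")
            records.append((ti, parts[1], parts[2]))
    if not records and not declared:
        raise TemporalNetworkError(f"{path}: empty temporal network file")

    if declared_t is not None:
        # a declared time-point count fixes the snapshot axis, so empty
        # snapshots survive a round trip; indices must already be dense
        bad = [ti for ti, _, _ in records if not 0 <= ti < declared_t]
        if bad:
            raise TemporalNetworkError(
                f"{path}: time index {bad[0]} outside declared range 0..{declared_t - 1}"
            )
        times = list(range(declared_t))
    else:
        times = sorted({ti for ti, _, _ in records}) or [0]
    dense = {ti: i for i, ti in enumerate(times)}
    snaps = [set() for _ in times]
    for ti, u, v in records:
        snaps[dense[ti]].add((u, v))
    return TemporalNetwork.from_edges(snaps, nodes=declared)


def _parse_edge_lines(path) -> tuple[set[Edge], set[str]]:
    edges: set[Edge] = set()
    declared: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.lower().startswith("#nodes:"):
                    body = line.split(":", 1)[1]
                    declared |= {tok.strip() for tok in body.split(",") if tok.strip()}
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise TemporalNetworkError(
                    f"{path}:{lineno}: expected at least 2 tab-separated fields"
                )
            edges.add(canonical_edge(parts[0], parts[1]))
    return edges, declared


def write_temporal_network(net: TemporalNetwork, path) -> None:
    """Write ``net`` as a long-format TSV (deterministic byte-for-byte).

    Edges are sorted by ``(time, u, v)`` with each edge in canonical order;
    a ``#nodes:`` header declares the full node set so isolated nodes
    round-trip.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#nodes: " + ",".join(net.nodes) + "\n")
        fh.write(f"#t: {net.t}\n")
        for i, edges in enumerate(net.snapshots):
            for u, v in sorted(edges):
                fh.write(f"{i}\t{u}\t{v}\n")


def read_expression_table(path) -> ExpressionTable:
    """Read a genes x conditions TSV (first column gene, rest conditions)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ExpressionTable.from_frame(frame)


def read_static_edges(path) -> list[Edge]:
    """Read a two-column static edge list TSV; extra columns are ignored."""
    edges, _ = _parse_edge_lines(path)
    return sorted(edges)


def build_condition_networks(
    expr: ExpressionTable,
    static_edges: Iterable[tuple[str, str]],
    cutoff: float,
) -> TemporalNetwork:
    """Threshold a static interaction network into condition snapshots.

    An edge ``(u, v)`` appears in snapshot ``i`` iff both endpoints have
    expression ``>= cutoff`` in condition ``i``.  Edges whose endpoints are
    absent from the expression table are dropped (counted in a log message).
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    idx = {g: i for i, g in enumerate(expr.genes)}
    kept: list[Edge] = []
    dropped = 0
    for u, v in static_edges:
        if u in idx and v in idx:
            kept.append(canonical_edge(u, v))
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d static edges with endpoints absent from expression", dropped)
    ok = expr.values >= cutoff  # genes x conditions
    snaps = []
    for c in range(len(expr.conditions)):
        snaps.append({e for e in kept if ok[idx[e[0]], c] and ok[idx[e[1]], c]})
    return TemporalNetwork.from_edges(snaps, nodes=expr.genes)


def interleave_time_points(n_points: int, offset: int, stride: int, take: int) -> list[int]:
    """Indices ``[offset, offset+stride, ...]`` of length ``take``.

    Used to carve non-overlapping interleaved condition series out of an
    ordered sequence of ``n_points`` conditions; series for offsets
    ``0..stride-1`` are pairwise disjoint.
    """
    if not (0 <= offset < stride):
        raise ValueError("need 0 <= offset < stride")
    if take < 1:
        raise ValueError("take must be >= 1")
    last = offset + (take - 1) * stride
    if last >= n_points:
        max_take = (n_points - 1 - offset) // stride + 1 if n_points > offset else 0
        raise ValueError(
            f"cannot take {take} points with offset {offset}, stride {stride} "
            f"from {n_points} points (max feasible take: {max_take})"
        )
    return [offset + i * stride for i in range(take)]
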