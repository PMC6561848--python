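"""Per-time-point node-pair similarity by propagating homology over topology.

For each time point the two snapshots induce a linear operator ``A_i`` on
pair-indexed vectors,

    A_i[(u,v),(w,z)] = 1 / (|N(w)| |N(z)|)   if w in N(u) and z in N(v),

which is column stochastic on columns whose two nodes both have positive
degree.  Homology scores H are mixed with topological support through the
damped iteration

    H^r = alpha * A_i @ H^{r-1} + (1 - alpha) * H^0,

whose fixed point S_i blends sequence similarity and neighbourhood
similarity; alpha = 0 reproduces pure homology.  Scores are aggregated over
time points as S(u, v) = sum_i S_i(u, v).

The operator is applied matrix-free: with B1, B2 the snapshot adjacency
matrices and d1, d2 the degree vectors, the action on an m x n pair matrix
X is ``B1 @ (X / outer(d1, d2)) @ B2`` (zero where a degree is zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .netio import TemporalNetwork

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.7
DEFAULT_TOL = 1e-9
DEFAULT_MAX_ITER = 200


class TopologySupport:
    """Matrix-free pair-similarity operator for one pair of snapshots."""

    def __init__(self, net1: TemporalNetwork, net2: TemporalNetwork, i: int):
        self.b1 = nx_adjacency(net1, i)
        self.b2 = nx_adjacency(net2, i)
        d1 = np.asarray(self.b1.sum(axis=1)).ravel()
        d2 = np.asarray(self.b2.sum(axis=1)).ravel()
        # 1/deg with 0 for isolated nodes: their columns of A_i are all zero.
        self.inv_d1 = np.divide(1.0, d1, out=np.zeros_like(d1, dtype=float), where=d1 > 0)
        self.inv_d2 = np.divide(1.0, d2, out=np.zeros_like(d2, dtype=float), where=d2 > 0)

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Return ``A_i @ x`` for a pair matrix x of shape (m, n)."""
        scaled = (x * self.inv_d1[:, None]) * self.inv_d2[None, :]
        return self.b1 @ scaled @ self.b2

    def apply_adjoint(self, x: np.ndarray) -> np.ndarray:
        """Return ``A_i.T @ x``; column sums of A_i are ``apply_adjoint(ones)``."""
        return ((self.b1 @ x @ self.b2) * self.inv_d1[:, None]) * self.inv_d2[None, :]


def nx_adjacency(net: TemporalNetwork, i: int) -> sp.csr_matrix:
    """Sparse adjacency of snapshot ``i`` in the network's node order."""
    idx = {u: j for j, u in enumerate(net.nodes)}
    n = net.n_nodes
    rows, cols = [], []
    for u, v in net.snapshots[i]:
        rows += [idx[u], idx[v]]
        cols += [idx[v], idx[u]]
    data = np.ones(len(rows))
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def topology_support(net1: TemporalNetwork, net2: TemporalNetwork, i: int) -> TopologySupport:
    """Build the pair-similarity operator A_i for time point ``i``."""
    return TopologySupport(net1, net2, i)


def propagate(
    op: TopologySupport,
    h0: np.ndarray,
    alpha: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, bool]:
    """Iterate ``H^r = alpha * A @ H^{r-1} + (1-alpha) * H^0`` to its fixed point.

    Returns the converged pair matrix and a convergence flag.  The iteration
    stops when the max-norm change drops to ``tol`` or after ``max_iter``
    steps; alpha = 0 returns ``h0`` exactly after one step.  For alpha < 1
    the map is a contraction (A is column stochastic on its support), so the
    fixed point solves ``(I - alpha A) x = (1 - alpha) h0``.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if tol <= 0:
        raise ValueError("tol must be positive")
    h = h0.copy()
    if alpha == 0.0:
        return h, True
    base = (1.0 - alpha) * h0
    for r in range(1, max_iter + 1):
        nxt = alpha * op.apply(h) + base
        resid = float(np.max(np.abs(nxt - h)))
        h = nxt
        if resid <= tol:
            logger.debug("propagation converged in %d iterations (residual %.3g)", r, resid)
            return h, True
    logger.warning(
        "propagation did not reach tol=%.3g in %d iterations (residual %.3g)",
        tol, max_iter, resid,
    )
    return h, False


@dataclass
class ScoreSet:
    """Homology, per-time similarity vectors S_i and their aggregate S.

    ``per_time`` and ``aggregate`` live on the normalized scale: the raw
    homology matrix is scaled to sum to 1 before propagation (recorded in
    ``scale``) so the stopping tolerance is scale-free.
    """

    query_nodes: tuple[str, ...]
    target_nodes: tuple[str, ...]
    homology: np.ndarray = field(repr=False)
    per_time: list[np.ndarray] = field(repr=False)
    aggregate: np.ndarray = field(repr=False)
    alpha: float = DEFAULT_ALPHA
    scale: float = 1.0
    converged: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        self._qidx = {u: i for i, u in enumerate(self.query_nodes)}
        self._tidx = {v: i for i, v in enumerate(self.target_nodes)}

    @property
    def t(self) -> int:
        return len(self.per_time)

    def query_index(self, u: str) -> int:
        return self._qidx[u]

    def target_index(self, v: str) -> int:
        return self._tidx[v]

    def pair_score(self, i: int, u: str, v: str) -> float:
        """S_i(u, v) for labelled nodes; missing labels raise KeyError."""
        return float(self.per_time[i][self._qidx[u], self._tidx[v]])


def score_all_time_points(
    net1: TemporalNetwork,
    net2: TemporalNetwork,
    homology: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ScoreSet:
    """Run propagation at every time point and aggregate over time.

    ``homology`` is indexed query-nodes x target-nodes in the networks' node
    orders and must be non-negative and finite.
    """
    if net1.t != net2.t:
        raise ValueError(f"time-point mismatch: query t={net1.t}, target t={net2.t}")
    homology = np.asarray(homology, dtype=float)
    if homology.shape != (net1.n_nodes, net2.n_nodes):
        raise ValueError("homology matrix shape does not match the node sets")
    if not np.all(np.isfinite(homology)) or np.any(homology < 0):
        raise ValueError("homology scores must be finite and non-negative")
    total = float(homology.sum())
    scale = total if total > 0 else 1.0
    h0 = homology / scale
    per_time, flags = [], []
    for i in range(net1.t):
        op = topology_support(net1, net2, i)
        s_i, ok = propagate(op, h0, alpha, tol=tol, max_iter=max_iter)
        per_time.append(s_i)
        flags.append(ok)
    aggregate = np.sum(per_time, axis=0)
    return ScoreSet(
        query_nodes=net1.nodes,
        target_nodes=net2.nodes,
        homology=homology,
        per_time=per_time,
        aggregate=aggregate,
        alpha=alpha,
        scale=scale,
        converged=tuple(flags),
    )


def read_homology(path, query_nodes, target_nodes) -> np.ndarray:
    """Read a ``query<TAB>target<TAB>score`` TSV into a dense matrix.

    Pairs absent from the file score 0; rows naming unknown nodes raise.
    """
    qidx = {u: i for i, u in enumerate(query_nodes)}
    tidx = {v: i for i, v in enumerate(target_nodes)}
    h = np.zeros((len(qidx), len(tidx)))
    frame = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["query", "target", "score"],
        dtype={"query": str, "target": str, "score": float},
    )
    for row in frame.itertuples(index=False):
        if row.query not in qidx:
            raise KeyError(f"unknown query node {row.query!r} in {path}")
        if row.target not in tidx:
            raise KeyError(f"unknown target node {row.target!r} in {path}")
        h[qidx[row.query], tidx[row.target]] = row.score
    return h


def write_homology(path, query_nodes, target_nodes, h: np.ndarray) -> None:
    """Write the nonzero entries of a homology matrix as a TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#query\ttarget\tscore\n")
        for i, u in enumerate(query_nodes):
            for j, v in enumerate(target_nodes):
                if h[i, j] != 0:
                    fh.write(f"{u}\t{v}\t{h[i, j]:.12g}\n")


def write_scores(path, scores: ScoreSet) -> None:
    """Write aggregate pair scores (12 significant digits) as a TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#query\ttarget\taggregate_score\n")
        for i, u in enumerate(scores.query_nodes):
            for j, v in enumerate(scores.target_nodes):
                fh.write(f"{u}\t{v}\t{scores.aggregate[i, j]:.12g}\n")
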