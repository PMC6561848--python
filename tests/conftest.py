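"""Shared randomized-instance builders for the test suite."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from temponet import Alignment, ScoreSet, TemporalNetwork, score_all_time_points


def random_temporal_network(rng, n_nodes=None, t=None, p=0.3, prefix="n") -> TemporalNetwork:
    """A random temporal network with independent G(n, p) snapshots."""
    n_nodes = n_nodes or int(rng.integers(2, 9))
    t = t or int(rng.integers(1, 4))
    nodes = [f"{prefix}{i}" for i in range(n_nodes)]
    snaps = []
    for _ in range(t):
        edges = {
            (nodes[i], nodes[j])
            for i in range(n_nodes)
            for j in range(i + 1, n_nodes)
            if rng.random() < p
        }
        snaps.append(edges)
    return TemporalNetwork.from_edges(snaps, nodes=nodes)


def random_pair(rng, m=None, n=None, t=None, alpha=0.7):
    """A random (query, target, ScoreSet) triple with m <= n."""
    m = m or int(rng.integers(2, 6))
    n = n or int(rng.integers(m, m + 4))
    t = t or int(rng.integers(1, 4))
    net1 = random_temporal_network(rng, n_nodes=m, t=t, prefix="q")
    net2 = random_temporal_network(rng, n_nodes=n, t=t, prefix="t")
    h = rng.random((m, n))
    scores = score_all_time_points(net1, net2, h, alpha=alpha)
    return net1, net2, scores


def random_injection(rng, scores: ScoreSet) -> Alignment:
    """A uniform random injective alignment for the given score set."""
    cols = rng.choice(len(scores.target_nodes), size=len(scores.query_nodes), replace=False)
    mapping = {u: scores.target_nodes[c] for u, c in zip(scores.query_nodes, cols)}
    return Alignment.from_mapping(mapping, scores.target_nodes)


def naive_alignment_score(net1, net2, scores, psi, delta) -> float:
    """From-first-principles score: explicit induced subgraph + BFS count."""
    total = 0.0
    image = {v for _, v in psi.psi}
    for i in range(net1.t):
        sim = sum(
            scores.per_time[i][scores.query_index(u), scores.target_index(v)]
            for u, v in psi.psi
        )
        g = nx.Graph()
        g.add_nodes_from(image)
        g.add_edges_from(
            (a, b) for a, b in net2.snapshots[i] if a in image and b in image
        )
        total += sim - delta * (nx.number_connected_components(g) - 1)
    return float(total)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
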