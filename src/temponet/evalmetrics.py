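"""Evaluation measures for temporal alignments.

* **recovered region** — percentage of query nodes mapped to their planted
  origin target nodes (requires a ground-truth map, so it is a
  synthetic-data / self-alignment measure);
* **ICS** (induced conserved structure) — per time point, the fraction of
  edges of the induced target subnetwork of the image that are matched by
  a query edge; summed over time points, so the total lies in [0, t];
* **EC** (edge correctness) — per time point, the fraction of query edges
  conserved under the mapping; summed over time points;
* **z-score** — the alignment score compared against the score
  distribution of uniformly random injective maps of the query into the
  target (default 1000 draws).

Per-time terms with a zero denominator (no induced edges for ICS, no query
edges for EC) contribute 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .align import Alignment, ScoreBreakdown, alignment_score, induced_subnetwork
from .netio import TemporalNetwork, canonical_edge
from .simscore import ScoreSet

logger = logging.getLogger(__name__)

DEFAULT_N_RANDOM = 1000


@dataclass(frozen=True)
class EvalReport:
    """Bundle of evaluation measures for one alignment."""

    recovered_region: float | None
    ics: float
    ec: float
    zscore: float | None
    n_random: int
    random_mean: float | None
    random_sd: float | None
    score: float
    t: int


def recovered_region(psi: Alignment, truth: dict) -> float:
    """Percentage of query nodes aligned to their planted origin."""
    mapping = psi.mapping
    missing = set(mapping) - set(truth)
    if missing:
        raise KeyError(f"truth map lacks query nodes: {sorted(missing)[:3]}")
    hits = sum(1 for u, v in mapping.items() if truth[u] == v)
    return 100.0 * hits / len(mapping)


def _conserved_per_time(net1, net2, psi):
    mapping = psi.mapping
    image = psi.image
    for i in range(net1.t):
        conserved = sum(
            1
            for u, v in net1.snapshots[i]
            if canonical_edge(mapping[u], mapping[v]) in net2.snapshots[i]
        )
        induced_edges = induced_subnetwork(net2.graph(i), image).number_of_edges()
        yield conserved, induced_edges, len(net1.snapshots[i])


def ics(net1: TemporalNetwork, net2: TemporalNetwork, psi: Alignment) -> float:
    """Induced conserved structure, summed over time points."""
    if net1.t != net2.t:
        raise ValueError("networks must share the number of time points")
    return sum(
        c / d for c, d, _ in _conserved_per_time(net1, net2, psi) if d > 0
    )


def ec(net1: TemporalNetwork, net2: TemporalNetwork, psi: Alignment) -> float:
    """Edge correctness, summed over time points."""
    if net1.t != net2.t:
        raise ValueError("networks must share the number of time points")
    return sum(
        c / e for c, _, e in _conserved_per_time(net1, net2, psi) if e > 0
    )


def random_alignment(query_nodes, target_nodes, rng: np.random.Generator) -> Alignment:
    """Uniform random injective map of the query into the target."""
    target_nodes = tuple(target_nodes)
    cols = rng.choice(len(target_nodes), size=len(tuple(query_nodes)), replace=False)
    mapping = {u: target_nodes[c] for u, c in zip(query_nodes, cols)}
    return Alignment.from_mapping(mapping, target_nodes)


def zscore(
    net1: TemporalNetwork,
    net2: TemporalNetwork,
    scores: ScoreSet,
    psi: Alignment,
    delta: float,
    n_random: int = DEFAULT_N_RANDOM,
    seed=None,
) -> tuple[float, float, float]:
    """Significance of an alignment score against a random-map null.

    Draws ``n_random`` uniform injective maps of the query node set into
    the target node set, scores each with the same delta, and returns
    ``(z, null_mean, null_sd)`` with ``z = (S* - mean) / sd``.
    """
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = alignment_score(net1, net2, scores, psi, delta).total
    # the null is scored with the same objective, but with precomputed
    # per-time adjacency so 1000 draws stay cheap at paper scale
    m = len(scores.query_nodes)
    n = len(scores.target_nodes)
    nbrs = []
    for i in range(net2.t):
        nb: dict[str, list] = {v: [] for v in scores.target_nodes}
        for a, b in net2.snapshots[i]:
            nb[a].append(b)
            nb[b].append(a)
        nbrs.append(nb)
    rows = np.arange(m)
    draws = np.empty(n_random)
    for r in range(n_random):
        cols = rng.choice(n, size=m, replace=False)
        image = {scores.target_nodes[c] for c in cols}
        total = 0.0
        for i in range(net2.t):
            sim = float(scores.per_time[i][rows, cols].sum())
            total += sim - delta * (_ncc_of(image, nbrs[i]) - 1)
        draws[r] = total
    mean = float(draws.mean())
    sd = float(draws.std(ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate null: all random alignments score identically")
    return (observed - mean) / sd, mean, sd


def _ncc_of(image: set, nbrs: dict) -> int:
    seen: set = set()
    comps = 0
    for s in image:
        if s in seen:
            continue
        comps += 1
        seen.add(s)
        stack = [s]
        while stack:
            x = stack.pop()
            for y in nbrs[x]:
                if y in image and y not in seen:
                    seen.add(y)
                    stack.append(y)
    return comps


def impose_static_alignment(
    per_time_psis,
    net1: TemporalNetwork,
    net2: TemporalNetwork,
    scores: ScoreSet,
    delta: float,
) -> tuple[list[ScoreBreakdown], float]:
    """Evaluate per-time-point alignments across *all* time points.

    This is the protocol for comparing static aligners on temporal data:
    each single-time-point alignment is imposed on every time point, scored
    with the temporal objective, and the average of the totals is reported.
    """
    per_time_psis = list(per_time_psis)
    if len(per_time_psis) != net1.t:
        raise ValueError("need exactly one alignment per time point")
    breakdowns = [
        alignment_score(net1, net2, scores, psi, delta) for psi in per_time_psis
    ]
    avg = float(np.mean([b.total for b in breakdowns]))
    return breakdowns, avg


def evaluate(
    net1: TemporalNetwork,
    net2: TemporalNetwork,
    scores: ScoreSet,
    psi: Alignment,
    delta: float,
    truth: dict | None = None,
    n_random: int = DEFAULT_N_RANDOM,
    seed=None,
) -> EvalReport:
    """Compute the full report; z-score is skipped when ``n_random`` == 0."""
    breakdown = alignment_score(net1, net2, scores, psi, delta)
    rr = recovered_region(psi, truth) if truth is not None else None
    ics_val = ics(net1, net2, psi)
    ec_val = ec(net1, net2, psi)
    logger.info("per-time means: ICS %.4f, EC %.4f", ics_val / net1.t, ec_val / net1.t)
    z = mean = sd = None
    if n_random:
        z, mean, sd = zscore(net1, net2, scores, psi, delta, n_random, seed)
    return EvalReport(
        recovered_region=rr,
        ics=ics_val,
        ec=ec_val,
        zscore=z,
        n_random=n_random,
        random_mean=mean,
        random_sd=sd,
        score=breakdown.total,
        t=net1.t,
    )
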