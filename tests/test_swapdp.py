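"""Swap application, the selection DP, and the coverage reduction."""

import itertools

import networkx as nx
import numpy as np
import pytest

from temponet import (
    Alignment,
    SwapSet,
    alignment_score,
    apply_swap,
    apply_swaps,
    best_single_swap,
    default_delta,
    default_k,
    induced_subnetwork,
    initial_alignment,
    mcp_reduction,
    ncc,
    score_all_time_points,
    select_swaps,
)
from temponet.netio import TemporalNetwork

from conftest import random_injection, random_pair


def exhaustive_best_score(net1, net2, scores, psi0, k, delta):
    """Brute-force optimum over all swap sets of size <= k."""
    gaps = sorted(psi0.gap_nodes)
    image = sorted(psi0.image)
    best = alignment_score(net1, net2, scores, psi0, delta).total
    for r in range(1, k + 1):
        for us in itertools.combinations(image, r):
            for vs in itertools.permutations(gaps, r):
                psi = apply_swaps(psi0, SwapSet(pairs=tuple(zip(us, vs))))
                best = max(best, alignment_score(net1, net2, scores, psi, delta).total)
    return best


class TestApplySwap:
    def test_swap_then_swap_back_restores(self, rng):
        _, net2, scores = random_pair(rng, m=3, n=6)
        psi = random_injection(rng, scores)
        u = sorted(psi.image)[0]
        v = sorted(psi.gap_nodes)[0]
        assert apply_swap(apply_swap(psi, u, v), v, u) == psi

    def test_swap_reassigns_the_query_node(self):
        psi = Alignment.from_mapping({"a11": "b11"}, ["b11", "b14"])
        psi2 = apply_swap(psi, "b11", "b14")
        assert psi2.mapping == {"a11": "b14"}
        assert psi2.gap_nodes == {"b11"}

    def test_disjoint_swaps_commute(self, rng):
        for _ in range(20):
            _, net2, scores = random_pair(rng, m=3, n=7)
            psi = random_injection(rng, scores)
            (u1, u2) = sorted(psi.image)[:2]
            (v1, v2) = sorted(psi.gap_nodes)[:2]
            a = apply_swap(apply_swap(psi, u1, v1), u2, v2)
            b = apply_swap(apply_swap(psi, u2, v2), u1, v1)
            assert a == b

    def test_invalid_nodes_rejected(self, rng):
        _, _, scores = random_pair(rng, m=2, n=4)
        psi = random_injection(rng, scores)
        v = sorted(psi.gap_nodes)[0]
        with pytest.raises(ValueError):
            apply_swap(psi, v, v)  # not an aligned node
        u = sorted(psi.image)[0]
        with pytest.raises(ValueError):
            apply_swap(psi, u, u)  # not a gap node


class TestSwapSetInvariants:
    def test_duplicate_out_nodes_rejected(self):
        with pytest.raises(ValueError):
            SwapSet(pairs=(("u", "v1"), ("u", "v2")))

    def test_duplicate_in_nodes_rejected(self):
        with pytest.raises(ValueError):
            SwapSet(pairs=(("u1", "v"), ("u2", "v")))

    def test_node_on_both_sides_rejected(self):
        with pytest.raises(ValueError):
            SwapSet(pairs=(("a", "b"), ("b", "c")))

    def test_application_order_is_irrelevant(self, rng):
        _, _, scores = random_pair(rng, m=3, n=8)
        psi = random_injection(rng, scores)
        us = sorted(psi.image)[:3]
        vs = sorted(psi.gap_nodes)[:3]
        pairs = tuple(zip(us, vs))
        for perm in itertools.permutations(pairs):
            assert apply_swaps(psi, SwapSet(pairs=perm)) == apply_swaps(
                psi, SwapSet(pairs=pairs)
            )


class TestBestSingleSwap:
    def test_single_gap_node_is_chosen(self, rng):
        net1, net2, scores = random_pair(rng, m=3, n=4)
        psi = random_injection(rng, scores)
        u = sorted(psi.image)[0]
        (v,) = psi.gap_nodes
        swaps, score = best_single_swap(net1, net2, scores, psi, u, delta=1.0)
        assert swaps.pairs == ((u, v),)
        assert score == pytest.approx(
            alignment_score(net1, net2, scores, apply_swap(psi, u, v), 1.0).total
        )

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(10):
            net1, net2, scores = random_pair(rng, m=3, n=6)
            psi = random_injection(rng, scores)
            delta = default_delta(scores)
            u = sorted(psi.image)[int(rng.integers(3))]
            _, score = best_single_swap(net1, net2, scores, psi, u, delta)
            best = max(
                alignment_score(net1, net2, scores, apply_swap(psi, u, v), delta).total
                for v in psi.gap_nodes
            )
            assert score == pytest.approx(best)

    def test_component_merging_swap_preferred(self):
        # two 2-cliques in the image, one gap node bridging them: with a
        # dominant delta the bridge swap wins over similarity
        net1 = TemporalNetwork.from_edges(
            [{("q0", "q1"), ("q1", "q2"), ("q2", "q3")}]
        )
        net2 = TemporalNetwork.from_edges(
            [{("t0", "t1"), ("t2", "t3"), ("t1", "t4"), ("t2", "t4"), ("t4", "t5")}]
        )
        h = np.zeros((4, 6))
        h[:, :4] = 0.1
        scores = score_all_time_points(net1, net2, h, alpha=0.0)
        psi = Alignment.from_mapping(
            {"q0": "t0", "q1": "t1", "q2": "t2", "q3": "t3"}, net2.nodes
        )
        delta = 10 * default_delta(scores)
        swaps, _ = best_single_swap(net1, net2, scores, psi, "t0", delta)
        assert swaps.pairs == (("t0", "t4"),)  # t4 merges the two components


class TestSelectSwaps:
    def test_k_one_equals_exhaustive_single_swap_optimum(self, rng):
        for _ in range(10):
            net1, net2, scores = random_pair(rng, m=3, n=6)
            psi0 = initial_alignment(scores)
            delta = default_delta(scores)
            res = select_swaps(net1, net2, scores, psi0, 1, delta)
            assert res.breakdown.total == pytest.approx(
                exhaustive_best_score(net1, net2, scores, psi0, 1, delta)
            )

    def test_sandwich_on_tiny_instances(self, rng):
        for _ in range(10):
            m = int(rng.integers(2, 5))
            n = int(rng.integers(m + 2, 8))
            net1, net2, scores = random_pair(rng, m=m, n=n, t=int(rng.integers(1, 3)))
            psi0 = initial_alignment(scores)
            delta = default_delta(scores)
            k = min(2, len(psi0.gap_nodes))
            res = select_swaps(net1, net2, scores, psi0, k, delta)
            assert res.breakdown.total >= res.initial_score - 1e-12
            assert res.breakdown.total <= (
                exhaustive_best_score(net1, net2, scores, psi0, k, delta) + 1e-9
            )

    def test_reported_score_matches_from_scratch_recomputation(self, rng):
        for _ in range(5):
            net1, net2, scores = random_pair(rng, m=4, n=9, t=2)
            psi0 = initial_alignment(scores)
            delta = default_delta(scores)
            res = select_swaps(net1, net2, scores, psi0, 2, delta)
            recomputed = alignment_score(
                net1, net2, scores, apply_swaps(psi0, res.swaps), delta
            )
            assert res.breakdown.total == pytest.approx(recomputed.total)
            assert res.alignment == apply_swaps(psi0, res.swaps)

    def test_connected_image_with_dominant_delta_changes_nothing(self, rng):
        net1 = TemporalNetwork.from_edges([{("q0", "q1")}])
        net2 = TemporalNetwork.from_edges([{("t0", "t1"), ("t1", "t2"), ("t2", "t0")}])
        h = np.zeros((2, 3))
        h[0, 0] = h[1, 1] = 1.0
        scores = score_all_time_points(net1, net2, h, alpha=0.0)
        psi0 = initial_alignment(scores)
        delta = default_delta(scores)
        res = select_swaps(net1, net2, scores, psi0, 1, delta)
        assert res.breakdown.total == pytest.approx(res.initial_score)
        assert len(res.swaps) == 0

    def test_k_out_of_range_rejected(self, rng):
        net1, net2, scores = random_pair(rng, m=3, n=5)
        psi0 = initial_alignment(scores)
        with pytest.raises(ValueError):
            select_swaps(net1, net2, scores, psi0, 0, 1.0)
        with pytest.raises(ValueError):
            select_swaps(net1, net2, scores, psi0, 3, 1.0)

    def test_iteration_best_is_monotone(self, rng):
        for _ in range(5):
            net1, net2, scores = random_pair(rng, m=4, n=9, t=2)
            psi0 = initial_alignment(scores)
            delta = default_delta(scores)
            res = select_swaps(net1, net2, scores, psi0, 3, delta)
            diffs = np.diff(res.iteration_best)
            assert np.all(diffs >= -1e-12)
            assert res.breakdown.total >= res.initial_score - 1e-12


class TestDefaultK:
    def test_connected_image_floors_at_one(self):
        net2 = TemporalNetwork.from_edges([{("t0", "t1"), ("t1", "t2")}])
        psi = Alignment.from_mapping({"q0": "t0", "q1": "t1"}, net2.nodes)
        assert default_k(net2, psi) == 1

    def test_worst_time_point_minus_one(self):
        snaps = [
            {("t0", "t1"), ("t2", "t3"), ("t4", "t5")},  # 3 components of image
            {("t0", "t1"), ("t1", "t2"), ("t2", "t3"), ("t3", "t4"), ("t4", "t5")},
        ]
        net2 = TemporalNetwork.from_edges(snaps, nodes=[f"t{i}" for i in range(8)])
        psi = Alignment.from_mapping(
            {f"q{i}": f"t{i}" for i in range(6)}, net2.nodes
        )
        assert default_k(net2, psi) == 2

    def test_capped_at_gap_count(self):
        net2 = TemporalNetwork.from_edges(
            [set()], nodes=[f"t{i}" for i in range(6)]
        )
        psi = Alignment.from_mapping(
            {f"q{i}": f"t{i}" for i in range(5)}, net2.nodes
        )  # 5 isolated aligned nodes -> NCC 5, but only 1 gap node
        assert default_k(net2, psi) == 1


class TestMcpReduction:
    def test_initial_component_count_is_n_plus_m(self, rng):
        sets = [{0, 1}, {1, 2}, {3}]
        g, aligned, gaps = mcp_reduction(sets, k=2)
        n = len({0, 1, 2, 3})
        m = len(sets)
        sub = induced_subnetwork(g, aligned)
        assert sub.number_of_edges() == 0
        assert ncc(sub) == n + m

    def test_swapping_covering_set_reaches_beta(self):
        sets = [{0, 1, 2, 3}]
        g, aligned, gaps = mcp_reduction(sets, k=1)
        # swap f0 in for b0: all 4 elements join f0's component
        swapped = (set(aligned) - {"b0"}) | {"f0"}
        assert ncc(induced_subnetwork(g, swapped)) == 1  # m-1+1 with m=1

    def test_beta_identity_on_hand_instance(self):
        sets = [{0, 1}, {2}, {0, 3}]
        m, n, k = 3, 4, 2
        g, aligned, gaps = mcp_reduction(sets, k=k)
        # best coverage with 2 sets: {0,1} + {0,3} -> tau = 3
        swapped = (set(aligned) - {"b0", "b1"}) | {"f0", "f2"}
        beta = ncc(induced_subnetwork(g, swapped))
        assert beta == (m + n - k + 1) - 3

    def test_gap_nodes_form_a_clique(self):
        g, _, gaps = mcp_reduction([{0}, {1}, {2}], k=1)
        sub = induced_subnetwork(g, gaps)
        assert sub.number_of_edges() == 3
        assert ncc(sub) == 1
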