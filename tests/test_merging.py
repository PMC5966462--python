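"""Merge phase: modularity bookkeeping, SIM gating, greedy agglomeration."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from votecomm import (Partition, UndirectedGraph, best_merge_pair,
                      community_similarity, delta_q, detect_communities,
                      init_merge_state, merge_pair, modularity, ring_of_cliques,
                      run_merging, run_voting)
from votecomm.merging import MergeContractError

from conftest import (community_sim_brute, modularity_double_sum, random_graph,
                      random_partition)


def state_partition(seed_partition, state, n):
    """Rebuild the current partition of a MergeState by replaying its merges."""
    groups = {i: list(c) for i, c in enumerate(seed_partition.communities)}
    for i, j, k in state.merges:
        groups[k] = groups.pop(i) + groups.pop(j)
    return Partition.from_communities(groups.values(), n)


class TestModularity:
    def test_single_community_is_zero(self, triangle):
        part = Partition.from_membership([0, 0, 0])
        assert modularity(triangle, part) == pytest.approx(0.0)

    def test_triangle_singletons(self, triangle):
        part = Partition.from_membership([0, 1, 2])
        assert modularity(triangle, part) == pytest.approx(-1 / 3)

    def test_edgeless_graph_rejected(self):
        g = UndirectedGraph.from_edge_labels([], extra_vertices=["a", "b"])
        with pytest.raises(ValueError):
            modularity(g, Partition.from_membership([0, 1]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_agrees_with_double_sum_oracle(self, seed):
        rng = random.Random(seed)
        g = random_graph(rng, rng.randint(3, 14), rng.uniform(0.2, 0.8))
        if g.n_edges == 0:
            return
        part = random_partition(rng, g.n_vertices, rng.randint(1, 4))
        assert modularity(g, part) == pytest.approx(
            modularity_double_sum(g, part), abs=1e-12)


class TestCommunitySimilarity:
    def test_two_singletons_reduce_to_vertex_similarity(self, triangle):
        from votecomm import vertex_similarity
        assert community_similarity(triangle, [0], [1]) == \
            pytest.approx(vertex_similarity(triangle, 0, 1))

    def test_no_shared_neighbourhood_gives_zero(self):
        g = UndirectedGraph.from_index_edges(4, [(0, 1), (2, 3)])
        assert community_similarity(g, [0, 1], [2, 3]) == 0.0

    def test_overlap_rejected(self, triangle):
        with pytest.raises(ValueError):
            community_similarity(triangle, [0, 1], [1, 2])

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_additive_over_disjoint_unions(self, seed):
        rng = random.Random(seed)
        g = random_graph(rng, 9, 0.4)
        a, b, c = [0, 1], [2, 3], [4, 5, 6]
        lhs = community_similarity(g, a + b, c)
        rhs = community_similarity(g, a, c) + community_similarity(g, b, c)
        assert lhs == pytest.approx(rhs)
        assert lhs == pytest.approx(community_sim_brute(g, a + b, c))


class TestInitMergeState:
    def test_triangle_singletons_bookkeeping(self, triangle):
        part = Partition.from_membership([0, 1, 2])
        state = init_merge_state(triangle, part)
        assert all(state.e_intra[i] == 0.0 for i in range(3))
        assert all(v == pytest.approx(1 / 6) for v in state.e_inter.values())
        assert all(state.a[i] == pytest.approx(1 / 3) for i in range(3))
        assert state.q_current == pytest.approx(-1 / 3)

    def test_connected_components_have_no_inter_mass(self):
        g = UndirectedGraph.from_index_edges(6, [(0, 1), (1, 2), (3, 4), (4, 5)])
        part = Partition.from_membership([0, 0, 0, 1, 1, 1])
        state = init_merge_state(g, part)
        assert state.e_inter == {}
        final, trace = run_merging(g, part)
        assert trace == [] and final.membership == part.membership

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_edge_mass_and_row_sum_invariants(self, seed):
        rng = random.Random(seed)
        g = random_graph(rng, rng.randint(4, 16), rng.uniform(0.2, 0.7))
        if g.n_edges == 0:
            return
        part = random_partition(rng, g.n_vertices, rng.randint(1, 5))
        state = init_merge_state(g, part)
        mass = sum(state.e_intra.values()) + 2 * sum(state.e_inter.values())
        assert mass == pytest.approx(1.0)
        for i in state.live:
            row = state.e_intra[i] + sum(
                v for (p, q), v in state.e_inter.items() if i in (p, q))
            assert state.a[i] == pytest.approx(row)
        assert state.q_current == pytest.approx(modularity(g, part))


class TestDeltaQ:
    def test_printed_formula(self):
        # direct substitution: e_ij=0.1, a_i=a_j=0.2 -> 2(0.1-0.04)=0.12
        from votecomm import MergeState
        state = MergeState(e_intra={0: 0.0, 1: 0.0}, e_inter={(0, 1): 0.1},
                           a={0: 0.2, 1: 0.2}, sim={(0, 1): 1.0},
                           live={0, 1}, q_current=0.0, next_id=2)
        assert delta_q(state, 0, 1) == pytest.approx(0.12)

    def test_zero_inter_mass_is_nonpositive(self):
        g = UndirectedGraph.from_index_edges(6, [(0, 1), (1, 2), (3, 4), (4, 5)])
        state = init_merge_state(g, Partition.from_membership([0, 0, 0, 1, 1, 1]))
        assert delta_q(state, 0, 1) == pytest.approx(-2 * state.a[0] * state.a[1])

    def test_dead_community_rejected(self, triangle):
        state = init_merge_state(triangle, Partition.from_membership([0, 1, 2]))
        with pytest.raises(MergeContractError):
            delta_q(state, 0, 7)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_equals_from_scratch_modularity_change(self, seed):
        rng = random.Random(seed)
        g = random_graph(rng, rng.randint(4, 14), rng.uniform(0.25, 0.7))
        if g.n_edges == 0:
            return
        part = random_partition(rng, g.n_vertices, rng.randint(2, 4))
        if part.n_communities < 2:
            return
        state = init_merge_state(g, part)
        i, j = rng.sample(sorted(state.live), 2)
        dq = delta_q(state, min(i, j), max(i, j))
        merged_membership = [min(i, j) if c == max(i, j) else c
                             for c in part.membership]
        merged = Partition.from_membership(merged_membership)
        assert dq == pytest.approx(modularity(g, merged) - modularity(g, part),
                                   abs=1e-12)


class TestBestMergePair:
    def test_none_when_no_similarity(self):
        g = UndirectedGraph.from_index_edges(4, [(0, 1), (2, 3)])
        state = init_merge_state(g, Partition.from_membership([0, 0, 1, 1]))
        assert best_merge_pair(state) is None

    def test_argmax_picks_larger_increment(self, bridged_cliques):
        g, _ = bridged_cliques
        seed, _ = run_voting(g)
        state = init_merge_state(g, seed)
        pair = best_merge_pair(state)
        brute = max(state.sim,
                    key=lambda p: (delta_q(state, *p), state.sim[p], -p[0], -p[1]))
        assert pair == brute

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_heap_equals_brute_force_argmax_throughout(self, seed):
        rng = random.Random(seed)
        g = random_graph(rng, rng.randint(5, 18), rng.uniform(0.2, 0.6))
        if g.n_edges == 0:
            return
        part = random_partition(rng, g.n_vertices, rng.randint(3, 6))
        state = init_merge_state(g, part)
        while True:
            pair = best_merge_pair(state)
            brute = max(state.sim,
                        key=lambda p: (delta_q(state, *p), state.sim[p], -p[0], -p[1]),
                        default=None)
            assert pair == brute
            if pair is None:
                break
            merge_pair(state, *pair)


class TestMergePair:
    def test_merging_everything_returns_q_to_zero(self):
        g = UndirectedGraph.from_index_edges(4, [(0, 1), (1, 2), (2, 3)])
        state = init_merge_state(g, Partition.from_membership([0, 0, 1, 1]))
        merge_pair(state, 0, 1)
        assert state.live == {2}
        assert state.q_current == pytest.approx(0.0)

    def test_ineligible_pair_rejected(self):
        g = UndirectedGraph.from_index_edges(4, [(0, 1), (2, 3)])
        state = init_merge_state(g, Partition.from_membership([0, 0, 1, 1]))
        with pytest.raises(MergeContractError):
            merge_pair(state, 0, 1)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_bookkeeping_stays_exact_through_all_merges(self, seed):
        """After every merge: conservation, SIM additivity, and q == from-scratch Q."""
        rng = random.Random(seed)
        g = random_graph(rng, rng.randint(6, 20), rng.uniform(0.2, 0.6))
        if g.n_edges == 0:
            return
        seed_part = random_partition(rng, g.n_vertices, rng.randint(3, 7))
        state = init_merge_state(g, seed_part)
        while True:
            pair = best_merge_pair(state)
            if pair is None:
                break
            a_sum_before = state.a[pair[0]] + state.a[pair[1]]
            merge_pair(state, *pair)
            new_id = state.merges[-1][2]
            assert state.a[new_id] == pytest.approx(a_sum_before)
            mass = sum(state.e_intra.values()) + 2 * sum(state.e_inter.values())
            assert mass == pytest.approx(1.0)
            current = state_partition(seed_part, state, g.n_vertices)
            assert state.q_current == pytest.approx(
                modularity(g, current), abs=1e-9)
            # SIM table additivity: every live pair matches brute-force recomputation
            groups = _groups(state, seed_part)
            for (i, j), s in state.sim.items():
                assert s == pytest.approx(
                    community_sim_brute(g, groups[i], groups[j]), abs=1e-9)


def _groups(state, seed_part):
    groups = {i: list(c) for i, c in enumerate(seed_part.communities)}
    for i, j, k in state.merges:
        groups[k] = groups.pop(i) + groups.pop(j)
    return groups


class TestRunMerging:
    def test_k4_singletons_merge_to_full_clique(self, k4):
        seed, _ = run_voting(k4)
        final, trace = run_merging(k4, seed)
        assert final.n_communities == 1
        assert modularity(k4, final) == pytest.approx(0.0)
        assert all(q <= 0 for _, _, _, q in trace[:-1])

    def test_bridged_cliques_stay_separate(self, bridged_cliques):
        g, truth = bridged_cliques
        seed, _ = run_voting(g)
        final, trace = run_merging(g, seed)
        assert sorted(map(sorted, final.communities)) == \
            sorted(map(sorted, truth.communities))
        # the single eligible merge has negative increment: 2(1/42 - 1/4) < 0
        assert len(trace) == 1 and trace[0][2] < 0

    def test_returned_q_never_below_seed_q(self):
        rng = random.Random(5)
        for _ in range(20):
            g = random_graph(rng, rng.randint(5, 18), rng.uniform(0.2, 0.6))
            if g.n_edges == 0:
                continue
            seed, _ = run_voting(g)
            final, _ = run_merging(g, seed)
            assert modularity(g, final) >= modularity(g, seed) - 1e-12

    def test_stop_at_nonpositive_policy(self, bridged_cliques):
        g, truth = bridged_cliques
        seed, _ = run_voting(g)
        final, trace = run_merging(g, seed, policy="stop_at_nonpositive")
        assert trace == []
        assert final.n_communities == 2

    def test_unknown_policy_rejected(self, triangle):
        with pytest.raises(ValueError):
            run_merging(triangle, Partition.from_membership([0, 1, 2]), policy="bogus")


class TestDetectCommunities:
    def test_bridged_cliques_end_to_end(self, bridged_cliques):
        g, truth = bridged_cliques
        part, trace, vote_state = detect_communities(g)
        assert sorted(map(sorted, part.communities)) == \
            sorted(map(sorted, truth.communities))

    def test_ring_of_four_triangles(self):
        g, truth = ring_of_cliques(4, 3)
        part, _, _ = detect_communities(g)
        assert sorted(map(sorted, part.communities)) == \
            sorted(map(sorted, truth.communities))

    def test_edgeless_graph_rejected(self):
        g = UndirectedGraph.from_edge_labels([], extra_vertices=["a", "b"])
        with pytest.raises(ValueError):
            detect_communities(g)

    def test_stable_under_vertex_relabelling(self):
        rng = random.Random(23)
        pairs = [(u, v) for u in range(16) for v in range(u + 1, 16)
                 if rng.random() < 0.3]
        g1 = UndirectedGraph.from_index_edges(16, pairs)
        perm = list(range(16))
        rng.shuffle(perm)
        g2 = UndirectedGraph.from_index_edges(
            16, [(perm[u], perm[v]) for u, v in pairs],
            labels=[str(perm.index(i)) for i in range(16)])
        p1, _, _ = detect_communities(g1)
        p2, _, _ = detect_communities(g2)
        c1 = sorted(sorted(g1.labels[v] for v in c) for c in p1.communities)
        c2 = sorted(sorted(g2.labels[v] for v in c) for c in p2.communities)
        assert c1 == c2

    def test_planted_structure_recovered_when_strong(self):
        from votecomm import planted_partition
        for seed in range(3):
            g, truth = planted_partition(4, 12, 0.9, 0.01, seed=seed)
            part, _, _ = detect_communities(g)
            assert sorted(map(sorted, part.communities)) == \
                sorted(map(sorted, truth.communities))
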