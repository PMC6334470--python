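"""Graph primitives: construction, density, induced marked subgraphs,
marked isomorphism, automorphisms, common neighbours."""

import logging
import math
from itertools import combinations, permutations

import pytest
from hypothesis import given, settings, strategies as st

from orbeq import (
    OrbitRepresentative,
    automorphism_group,
    build_graph,
    canonical_certificate,
    common_neighbour_count,
    density,
    generate_er,
    induced_marked_subgraph,
    marked_isomorphic,
)


class TestBuildGraph:
    def test_path_construction(self):
        g = build_graph([("a", "b"), ("b", "c")])
        assert (g.n, g.m) == (3, 2)

    def test_duplicate_undirected_edges_collapse(self):
        g = build_graph([("a", "b"), ("b", "a"), ("a", "b")])
        assert (g.n, g.m) == (2, 1)

    def test_self_loop_skipped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="orbeq.graph"):
            g = build_graph([("a", "a"), ("a", "b")])
        assert (g.n, g.m) == (2, 1)
        assert any("self-loop" in r.message for r in caplog.records)

    def test_self_loop_strict_mode_raises(self):
        with pytest.raises(ValueError):
            build_graph([("a", "a")], strict=True)

    def test_empty_input_is_valid(self):
        g = build_graph([])
        assert (g.n, g.m) == (0, 0)


class TestDensity:
    def test_complete_graph(self):
        g = build_graph([(i, j) for i in range(5) for j in range(i + 1, 5)])
        assert density(g) == 1.0

    def test_empty_graph(self):
        g = build_graph([], nodes=[0, 1, 2])
        assert density(g) == 0.0

    def test_path_three_nodes(self):
        assert density(build_graph([(0, 1), (1, 2)])) == pytest.approx(2 / 3)

    def test_undefined_below_two_nodes(self):
        with pytest.raises(ValueError):
            density(build_graph([], nodes=["a"]))


class TestInducedMarkedSubgraph:
    def test_full_triangle(self, triangle):
        rep = induced_marked_subgraph(triangle, {0, 1, 2}, 1)
        assert rep.k == 3 and rep.e == 3

    def test_disconnected_output_is_valid(self):
        g = build_graph([("a", "b"), ("b", "c")])
        rep = induced_marked_subgraph(g, {0, 2}, 0)
        assert rep.e == 0 and not rep.is_connected()

    def test_k4_minus_edge_span(self):
        # K4 minus edge {0,1}; subset spanning the missing edge is a path
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        edges.remove((0, 1))
        g = build_graph(edges)
        subset = {g.index[0], g.index[1], g.index[2]}
        rep = induced_marked_subgraph(g, subset, g.index[0])
        path_end = OrbitRepresentative(3, frozenset(((0, 1), (1, 2))), 0)
        assert marked_isomorphic(rep, path_end)

    def test_marked_outside_subset_rejected(self, triangle):
        with pytest.raises(ValueError):
            induced_marked_subgraph(triangle, {0, 1}, 2)


PATH3_END = OrbitRepresentative(3, frozenset(((0, 1), (1, 2))), 0)
PATH3_MID = OrbitRepresentative(3, frozenset(((0, 1), (1, 2))), 1)


class TestMarkedIsomorphism:
    def test_relabelled_path_ends_match(self):
        other = OrbitRepresentative(3, frozenset(((0, 2), (1, 2))), 1)
        assert marked_isomorphic(PATH3_END, other)
        assert canonical_certificate(PATH3_END) == canonical_certificate(other)

    def test_end_vs_middle_differ(self):
        assert not marked_isomorphic(PATH3_END, PATH3_MID)

    def test_eleven_classes_of_connected_4_node_marked_graphs(self):
        certs = set()
        pairs = list(combinations(range(4), 2))
        for bits in range(1 << 6):
            edges = frozenset(p for i, p in enumerate(pairs) if bits >> i & 1)
            for marked in range(4):
                rep = OrbitRepresentative(4, edges, marked)
                if rep.is_connected():
                    certs.add(canonical_certificate(rep))
        assert len(certs) == 11

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_certificate_invariant_under_relabelling(self, data):
        k = data.draw(st.integers(2, 5))
        pairs = list(combinations(range(k), 2))
        edges = frozenset(
            p for p in pairs if data.draw(st.booleans(), label=str(p)))
        marked = data.draw(st.integers(0, k - 1))
        rep = OrbitRepresentative(k, edges, marked)
        perm = data.draw(st.permutations(list(range(k))))
        assert canonical_certificate(rep) == canonical_certificate(
            rep.relabel(perm))


class TestAutomorphisms:
    @pytest.mark.parametrize(
        "edges, marked, size",
        [
            (tuple(combinations(range(4), 2)), 0, 6),  # K4: 3! on the rest
            (((0, 1), (1, 2)), 1, 2),                  # path middle: swap ends
            (((0, 1), (1, 2)), 0, 1),                  # path end: rigid
        ],
    )
    def test_group_sizes(self, edges, marked, size):
        rep = OrbitRepresentative(len(set(sum(edges, ()))), frozenset(edges),
                                  marked)
        assert len(automorphism_group(rep)) == size

    def test_group_closed_and_order_divides_factorial(self):
        for bits in range(1 << 6):
            pairs = list(combinations(range(4), 2))
            edges = frozenset(p for i, p in enumerate(pairs) if bits >> i & 1)
            rep = OrbitRepresentative(4, edges, 0)
            group = set(automorphism_group(rep))
            assert tuple(range(4)) in group
            assert math.factorial(3) % len(group) == 0
            for f in group:
                for h in group:
                    assert tuple(f[h[i]] for i in range(4)) in group


class TestCommonNeighbours:
    def test_triangle_pair(self, triangle):
        assert common_neighbour_count(triangle, {0, 1}) == 1

    def test_star_leaves_share_the_centre(self):
        g = build_graph([("c", i) for i in range(4)])
        leaves = [g.index[i] for i in range(4)]
        assert common_neighbour_count(g, leaves) == 1

    def test_matches_direct_intersection(self):
        g = generate_er(20, 60, 1)
        for u, v in [(0, 1), (3, 7), (10, 19)]:
            assert common_neighbour_count(g, {u, v}) == len(
                g.adj[u] & g.adj[v])

    def test_empty_subset_rejected(self, triangle):
        with pytest.raises(ValueError):
            common_neighbour_count(triangle, set())

    def test_antitone_in_the_subset(self):
        g = generate_er(15, 50, 2)
        for s in combinations(range(6), 2):
            for t in combinations(range(6), 3):
                if set(s) <= set(t):
                    assert common_neighbour_count(g, s) >= \
                        common_neighbour_count(g, t)
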