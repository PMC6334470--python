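"""The counting pipeline: common-neighbour table, direct counts, the
triangular solve, and instrumentation."""

from itertools import combinations

import pytest

from orbeq import (
    brute_force_degrees,
    build_graph,
    common_neighbour_count,
    count_orbits,
    enumerate_representatives,
    generate_er,
    precompute_common_neighbours,
    solve_system,
)
from orbeq.selection import select_equations
from orbeq.equations import generate_all_equations


class TestCommonNeighbourTable:
    def test_triangle_entries(self, triangle):
        table = precompute_common_neighbours(triangle, 4)
        for v in range(3):
            assert table.get((v,)) == 2
        for pair in combinations(range(3), 2):
            assert table.get(pair) == 1

    def test_star_entries(self):
        g = build_graph([("c", 1), ("c", 2), ("c", 3)])
        table = precompute_common_neighbours(g, 5)
        centre = g.index["c"]
        leaves = [g.index[i] for i in (1, 2, 3)]
        assert table.get((centre,)) == 3
        for leaf in leaves:
            assert table.get((leaf,)) == 1
        for pair in combinations(sorted(leaves), 2):
            assert table.get(pair) == 1
        assert table.get(tuple(sorted(leaves))) == 1
        # pairs containing the centre have no common neighbour: miss -> 0
        missing = tuple(sorted((centre, leaves[0])))
        assert table.get(missing) == 0

    def test_lookup_counter_counts_hits_and_misses(self, triangle):
        table = precompute_common_neighbours(triangle, 4)
        table.get((0,))
        table.get((0, 1, 2))  # miss
        assert table.lookups == 2

    def test_entries_match_direct_recomputation(self):
        g = generate_er(30, 120, 3)
        table = precompute_common_neighbours(g, 5)
        for key, value in table.counts.items():
            assert value == common_neighbour_count(g, key)
            assert value >= 1


class TestCountOrbits:
    def test_k5_host(self, k5, catalog5):
        matrix, _ = count_orbits(k5, 5, "first", 0)
        kk = catalog5.orbits_of_order(5)[-1]
        for v in range(5):
            for orbit in catalog5.orbits_of_order(5):
                assert matrix.degree(v, orbit) == (1 if orbit == kk else 0)

    def test_c5_host_only_the_cycle_orbit(self, c5, catalog5):
        matrix, _ = count_orbits(c5, 5, "fewest_args", 0)
        cycle_orbits = [
            i for i in catalog5.orbits_of_order(5)
            if catalog5.reps[i].e == 5
            and all(catalog5.reps[i].degree(v) == 2 for v in range(5))
        ]
        assert len(cycle_orbits) == 1
        for v in range(5):
            for orbit in catalog5.orbits_of_order(5):
                assert matrix.degree(v, orbit) == (
                    1 if orbit == cycle_orbits[0] else 0)

    @pytest.mark.parametrize("k", [4, 5])
    @pytest.mark.parametrize("strategy", [
        "first", "random", "fewest_terms", "most_terms",
        "fewest_args", "most_args", "auto"])
    def test_matches_oracle_on_er(self, k, strategy):
        g = generate_er(14, 40, 11)
        matrix, _ = count_orbits(g, k, strategy, seed=11)
        assert matrix.same_counts(brute_force_degrees(g, k))

    def test_row_sums_count_connected_subgraphs(self, catalog5):
        from orbeq.oracle import _is_connected_subset

        g = generate_er(12, 30, 4)
        matrix, _ = count_orbits(g, 5, "first", 0)
        for order in (3, 4, 5):
            cols = [matrix.orbit_indices.index(i)
                    for i in catalog5.orbits_of_order(order)]
            for v in range(g.n):
                expected = sum(
                    1 for sub in combinations(range(g.n), order)
                    if v in sub and _is_connected_subset(g, sub))
                assert int(matrix.data[v, cols].sum()) == expected

    def test_lookup_count_deterministic(self):
        g = generate_er(20, 80, 6)
        _, a = count_orbits(g, 5, "fewest_args", 0)
        _, b = count_orbits(g, 5, "fewest_args", 0)
        assert a.lookups == b.lookups and a.lookups > 0

    def test_small_k_rejected(self, triangle):
        with pytest.raises(ValueError):
            count_orbits(triangle, 2)

    def test_host_smaller_than_k_gives_zero_top_order(self, catalog5):
        g = build_graph([(0, 1), (1, 2)])
        matrix, _ = count_orbits(g, 5, "first", 0)
        cols = [matrix.orbit_indices.index(i)
                for i in catalog5.orbits_of_order(5)]
        assert int(matrix.data[:, cols].sum()) == 0


class TestSolveSystem:
    def test_all_zero_rhs_gives_all_zero_degrees(self, catalog4):
        candidates = generate_all_equations(4, catalog4)
        system = select_equations(candidates, "first")
        rhs = {eq.target: [0, 0] for eq in system.equations}
        known = {idx: [0, 0] for idx in range(len(catalog4.reps))
                 if catalog4.reps[idx].k in (2, 3)}
        known[catalog4.orbits_of_order(4)[-1]] = [0, 0]
        solved = solve_system(system, rhs, known)
        assert all(v == [0, 0] for v in solved.values())

    def test_inconsistent_rhs_is_a_hard_error(self, catalog4):
        # a negative or fractional back-substitution signals a bug, never
        # a silently wrong count
        candidates = generate_all_equations(4, catalog4)
        system = select_equations(candidates, "first")
        rhs = {e.target: [0] for e in system.equations}
        rhs[system.equations[0].target] = [-1]
        known = {idx: [0] for idx in range(len(catalog4.reps))
                 if catalog4.reps[idx].k in (2, 3)}
        known[catalog4.orbits_of_order(4)[-1]] = [0]
        with pytest.raises(ArithmeticError):
            solve_system(system, rhs, known)


def test_lookup_ordering_flips_with_density_small_scale():
    """The mechanism behind density-driven selection, at reduced size:
    sparse graphs favour fewest_args, dense graphs most_args."""
    def mean_lookups(density, strategy):
        total = 0
        for seed in range(3):
            m = round(density * 30 * 29 / 2)
            g = generate_er(30, m, seed)
            _, stats = count_orbits(g, 5, strategy, seed)
            total += stats.lookups
        return total / 3

    assert mean_lookups(0.2, "fewest_args") < mean_lookups(0.2, "most_args")
    assert mean_lookups(0.9, "fewest_args") > mean_lookups(0.9, "most_args")
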