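import pytest

from orbeq import (
    build_graph,
    common_neighbour_count,
    enumerate_representatives,
    generate_er,
    induced_marked_subgraph,
)


@pytest.fixture(scope="session")
def catalog4():
    return enumerate_representatives(4)


@pytest.fixture(scope="session")
def catalog5():
    return enumerate_representatives(5)


@pytest.fixture
def triangle():
    return build_graph([(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def c5():
    return build_graph([(i, (i + 1) % 5) for i in range(5)])


@pytest.fixture
def k5():
    return build_graph([(i, j) for i in range(5) for j in range(i + 1, 5)])


def er(n, m, seed):
    return generate_er(n, m, seed)


def rhs_value(g, eq, x, catalog):
    """Independent evaluation of an equation's RHS at node x: enumerate
    every (k-1)-subset containing x, keep instances of the equation's RHS
    representative, and sum c(...) - adjustment over the argument family
    using direct common-neighbour counting."""
    from itertools import combinations

    from orbeq.graph import find_marked_isomorphism

    omega = catalog.reps[eq.omega]
    size = omega.k
    total = 0
    for rest in combinations([v for v in range(g.n) if v != x], size - 1):
        subset = tuple(sorted((x,) + rest))
        rep = induced_marked_subgraph(g, subset, x)
        if not rep.is_connected():
            continue
        if catalog.get(rep) != eq.omega:
            continue
        f = find_marked_isomorphism(omega, rep)
        for sp, adj in zip(eq.argument_sets, eq.adjustments):
            hosts = [subset[f[v]] for v in sp]
            total += common_neighbour_count(g, hosts) - adj
    return total
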