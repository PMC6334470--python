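"""The counting pipeline.

Orbit degrees of orders 2..k-1 are counted directly: every connected node
subset of size < k is enumerated exactly once (extension enumeration over
bitmask adjacency) and classified, per marked node, against the catalog via
a memoized edge-mask table.  Each (k-1)-subset additionally feeds the
right-hand sides of the selected counting equations: every c(...) term is
retrieved from the precomputed common-neighbour table (one *lookup* per
retrieval — the instrumented quantity that equation selection minimises),
except terms with k-1 arguments, which are computed by on-the-fly adjacency
intersection and tallied separately.  The complete graphlet K_k is counted
directly from K_{k-1} instances, and the remaining order-k degrees follow
by exact integer back-substitution down the upper-triangular system.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .catalog import enumerate_representatives
from .equations import generate_all_equations
from .graph import (
    Graph,
    OrbitRepresentative,
    canonical_certificate,
    density,
    find_marked_isomorphism,
    _pair_bit,
)
from .selection import EquationSystem, resolve_auto, select_equations

__all__ = [
    "CommonNeighbourTable",
    "GraphletDegreeMatrix",
    "RunStats",
    "precompute_common_neighbours",
    "count_orbits",
    "solve_system",
]


class CommonNeighbourTable:
    """c(S) for every node tuple S (sizes 1..k-2) with at least one common
    neighbour; absent tuples read as 0.  Every retrieval counts as one
    lookup, hit or miss."""

    __slots__ = ("counts", "max_args", "lookups")

    def __init__(self, max_args: int) -> None:
        self.counts: dict[tuple[int, ...], int] = {}
        self.max_args = max_args
        self.lookups = 0

    def get(self, key: tuple[int, ...]) -> int:
        self.lookups += 1
        return self.counts.get(key, 0)

    def __len__(self) -> int:
        return len(self.counts)


def precompute_common_neighbours(g: Graph, k: int) -> CommonNeighbourTable:
    """One pass over each node's neighbourhood: every subset S of N(w) with
    1 <= |S| <= k-2 gains one common neighbour (w itself)."""
    if k < 3:
        raise ValueError("k must be >= 3")
    table = CommonNeighbourTable(max_args=k - 2)
    counts = table.counts
    for w in range(g.n):
        nbrs = sorted(g.adj[w])
        for size in range(1, min(k - 2, len(nbrs)) + 1):
            for s in combinations(nbrs, size):
                counts[s] = counts.get(s, 0) + 1
    return table


@dataclass
class GraphletDegreeMatrix:
    """node x orbit table of graphlet degrees o_i(v), orbits of orders 2..k."""

    node_names: list
    orbit_indices: list[int]
    data: np.ndarray  # (n, n_orbits) non-negative integers

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.data, index=self.node_names,
            columns=self.orbit_indices)

    def degree(self, node, orbit: int) -> int:
        i = self.node_names.index(node)
        j = self.orbit_indices.index(orbit)
        return int(self.data[i, j])

    def same_counts(self, other: "GraphletDegreeMatrix") -> bool:
        return (
            self.node_names == other.node_names
            and self.orbit_indices == other.orbit_indices
            and bool(np.array_equal(self.data, other.data))
        )


@dataclass
class RunStats:
    """Instrumentation of one counting run; the lookup count is
    deterministic given (graph, k, equation system)."""

    k: int
    n: int
    m: int
    density: float
    strategy: str
    resolved_strategy: str
    seed: int | None
    lookups: int = 0
    intersections: int = 0
    times: dict = field(default_factory=dict)


def _connected_subsets(amask: list[int], n: int, max_size: int):
    """Yield every connected node subset of size 2..max_size exactly once,
    as a sorted tuple.  Extension enumeration: subsets are grown from their
    minimum node, candidates restricted to exclusive neighbours with larger
    index, so each subset has a unique generation path."""
    for v in range(n):
        above = -1 << (v + 1)
        ext0 = amask[v] & above
        if not ext0:
            continue
        # stack entries: (nodes, extension mask, closed neighbourhood mask)
        stack = [((v,), ext0, amask[v] | (1 << v))]
        while stack:
            nodes, ext, nbr = stack.pop()
            size = len(nodes) + 1
            while ext:
                wbit = ext & -ext
                ext ^= wbit
                w = wbit.bit_length() - 1
                new_nodes = nodes + (w,)
                yield tuple(sorted(new_nodes))
                if size < max_size:
                    new_ext = ext | (amask[w] & ~nbr & above)
                    stack.append(
                        (new_nodes, new_ext, nbr | amask[w] | wbit))


def _classify_mask(catalog, size: int, emask: int):
    """For one induced edge pattern on ``size`` positions: per marked
    position, the catalog index and one embedding omega-label -> position."""
    edges = frozenset(
        (i, j) for i in range(size) for j in range(i + 1, size)
        if emask >> _pair_bit(i, j) & 1)
    out = []
    for p in range(size):
        rep = OrbitRepresentative(size, edges, p)
        idx = catalog.index_of(rep)
        emb = find_marked_isomorphism(catalog.reps[idx], rep)
        out.append((idx, tuple(emb)))
    return out


def solve_system(system: EquationSystem, rhs: dict[int, list[int]],
                 known: dict[int, list[int]]) -> dict[int, list[int]]:
    """Back-substitution in descending orbit index.

    ``known`` must hold the degrees of every denser orbit referenced by the
    LHS (including directly counted ones); division must be exact and the
    result non-negative, else the equations and search disagree.
    """
    known = dict(known)
    out: dict[int, list[int]] = {}
    for eq in system.equations:  # descending target index
        t = eq.target
        if t in known:
            continue
        acc = list(rhs[t])
        for j, c in eq.lhs:
            if j == t:
                ct = c
                continue
            dj = known[j]
            for x in range(len(acc)):
                acc[x] -= c * dj[x]
        for x in range(len(acc)):
            q, r = divmod(acc[x], ct)
            if r or q < 0:
                raise ArithmeticError(
                    f"non-integral or negative degree for orbit {t} at node "
                    f"{x}: {acc[x]}/{ct}")
            acc[x] = q
        known[t] = acc
        out[t] = acc
    return out


def count_orbits(g: Graph, k: int, strategy: str = "auto",
                 seed: int | None = 0) -> tuple[GraphletDegreeMatrix, RunStats]:
    """Graphlet degrees of all orbits of orders 2..k for every node."""
    if k < 3:
        raise ValueError("k must be >= 3")
    t_start = time.perf_counter()
    catalog = enumerate_representatives(k)
    candidates = generate_all_equations(k, catalog)
    dens = density(g) if g.n >= 2 else 0.0
    requested = strategy.replace("-", "_")
    resolved = resolve_auto(dens) if requested == "auto" else requested
    system = select_equations(candidates, resolved, seed)
    stats = RunStats(
        k=k, n=g.n, m=g.m, density=dens, strategy=requested,
        resolved_strategy=resolved, seed=seed)
    stats.times["setup"] = time.perf_counter() - t_start

    # --- common-neighbour precomputation -------------------------------
    t0 = time.perf_counter()
    table = precompute_common_neighbours(g, k)
    counts = table.counts
    counts_get = counts.get
    stats.times["table"] = time.perf_counter() - t0

    n = g.n
    amask = g.adj_masks()
    norb = len(catalog.reps)
    kk_idx = catalog.orbits_of_order(k)[-1]       # K_k: densest, max index

    # compile the selected equations by RHS representative; the complete
    # graphlet is counted directly, so its equation never accumulates
    eqs_by_omega: dict[int, list] = {}
    for eq in system.equations:
        if eq.target != kk_idx:
            eqs_by_omega.setdefault(eq.omega, []).append(eq)

    deg = [None] * norb
    for order in range(2, k):
        for idx in catalog.orbits_of_order(order):
            deg[idx] = [0] * n
    rhs_acc: dict[int, list[int]] = {
        eq.target: [0] * n for eq in system.equations}
    km1_complete_mask = (1 << (k - 1) * (k - 2) // 2) - 1
    kk_raw = [0] * n

    class_cache: dict[tuple[int, int], list] = {}
    plan_cache: dict[int, list] = {}
    max_args = k - 2

    def build_plan(emask: int) -> list:
        """Per marked position: the compiled RHS work for this pattern."""
        entry = class_cache.get((k - 1, emask))
        if entry is None:
            entry = _classify_mask(catalog, k - 1, emask)
            class_cache[(k - 1, emask)] = entry
        plans = []
        for oidx, emb in entry:
            work = []
            for eq in eqs_by_omega.get(oidx, ()):
                argpos = tuple(
                    tuple(sorted(emb[v] for v in sp))
                    for sp in eq.argument_sets)
                work.append(
                    (eq.target, argpos, eq.adjustments, eq.n_args))
            plans.append(work)
        return plans

    # --- subset scan: direct degrees + RHS accumulation ----------------
    t0 = time.perf_counter()
    lookups = 0
    intersections = 0
    sub_size = k - 1
    for nodes in _connected_subsets(amask, n, k - 1):
        size = len(nodes)
        emask = 0
        for i in range(size):
            ai = amask[nodes[i]]
            for j in range(i + 1, size):
                if ai >> nodes[j] & 1:
                    emask |= 1 << _pair_bit(i, j)
        key = (size, emask)
        entry = class_cache.get(key)
        if entry is None:
            entry = _classify_mask(catalog, size, emask)
            class_cache[key] = entry
        for p in range(size):
            deg[entry[p][0]][nodes[p]] += 1
        if size != sub_size:
            continue
        # complete (k-1)-subset: extend to K_k by a full-subset intersection
        if emask == km1_complete_mask:
            inter = amask[nodes[0]]
            for p in range(1, size):
                inter &= amask[nodes[p]]
            intersections += 1
            cnt = inter.bit_count()
            if cnt:
                for p in range(size):
                    kk_raw[nodes[p]] += cnt
        plans = plan_cache.get(emask)
        if plans is None:
            plans = build_plan(emask)
            plan_cache[emask] = plans
        for p in range(size):
            work = plans[p]
            if not work:
                continue
            x = nodes[p]
            for target, argpos, adjs, n_args in work:
                acc = rhs_acc[target]
                if n_args <= max_args:
                    for apos, adj_c in zip(argpos, adjs):
                        ckey = tuple(nodes[q] for q in apos)
                        lookups += 1
                        acc[x] += counts_get(ckey, 0) - adj_c
                else:
                    for apos, adj_c in zip(argpos, adjs):
                        inter = amask[nodes[apos[0]]]
                        for q in apos[1:]:
                            inter &= amask[nodes[q]]
                        intersections += 1
                        acc[x] += inter.bit_count() - adj_c
    table.lookups += lookups
    stats.times["search"] = time.perf_counter() - t0

    # --- K_k directly, then the triangular solve -----------------------
    t0 = time.perf_counter()
    kk_deg = [0] * n
    for x in range(n):
        q, r = divmod(kk_raw[x], k - 1)
        if r:
            raise ArithmeticError(
                f"K_{k} count at node {x} not divisible by {k - 1}")
        kk_deg[x] = q
    deg[kk_idx] = kk_deg
    known = {idx: deg[idx] for idx in range(norb)
             if deg[idx] is not None and catalog.reps[idx].k >= 2}
    solved = solve_system(system, rhs_acc, known)
    for idx, row in solved.items():
        deg[idx] = row
    stats.times["solve"] = time.perf_counter() - t0

    stats.lookups = lookups
    stats.intersections = intersections
    orbit_indices = [i for i in range(norb) if catalog.reps[i].k >= 2]
    data = np.array([deg[i] for i in orbit_indices], dtype=np.int64).T
    if data.size == 0:
        data = np.zeros((n, len(orbit_indices)), dtype=np.int64)
    matrix = GraphletDegreeMatrix(
        node_names=list(g.names), orbit_indices=orbit_indices, data=data)
    return matrix, stats
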