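"""Graph and marked-graphlet primitives.

An undirected simple graph G = (V, E) is stored with a dense integer index
per node (chosen at creation, in order of first appearance) and per-node
adjacency sets.  Graphlets — small connected induced subgraphs — are handled
through :class:`OrbitRepresentative`: a graphlet with one *marked* node,
which stands for a whole automorphism orbit.  Two representatives are
equivalent when a marked-preserving isomorphism exists between them; a
brute-force canonical certificate realises that equivalence as equality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Hashable, Iterable, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "OrbitRepresentative",
    "build_graph",
    "density",
    "induced_marked_subgraph",
    "marked_isomorphic",
    "canonical_certificate",
    "automorphism_group",
    "common_neighbour_count",
]


class Graph:
    """Undirected simple graph with ordered node indices and adjacency sets.

    Attributes
    ----------
    names : list
        Node identifiers, position = dense index (a bijection onto 0..n-1).
    index : dict
        Reverse lookup, name -> index.
    adj : list[set[int]]
        Symmetric adjacency, no self-loops.
    """

    __slots__ = ("names", "index", "adj", "_adj_mask")

    def __init__(self) -> None:
        self.names: list[Hashable] = []
        self.index: dict[Hashable, int] = {}
        self.adj: list[set[int]] = []
        self._adj_mask: list[int] | None = None

    @property
    def n(self) -> int:
        """Order: number of nodes."""
        return len(self.names)

    @property
    def m(self) -> int:
        """Size: number of edges."""
        return sum(len(a) for a in self.adj) // 2

    def add_node(self, name: Hashable) -> int:
        i = self.index.get(name)
        if i is None:
            i = len(self.names)
            self.index[name] = i
            self.names.append(name)
            self.adj.append(set())
            self._adj_mask = None
        return i

    def add_edge(self, u: Hashable, v: Hashable) -> bool:
        """Add the undirected edge {u, v}; returns False on a duplicate."""
        i, j = self.add_node(u), self.add_node(v)
        if i == j:
            raise ValueError(f"self-loop on node {u!r}")
        if j in self.adj[i]:
            return False
        self.adj[i].add(j)
        self.adj[j].add(i)
        self._adj_mask = None
        return True

    def has_edge_idx(self, i: int, j: int) -> bool:
        return j in self.adj[i]

    def edges_idx(self) -> list[tuple[int, int]]:
        return [(i, j) for i in range(self.n) for j in self.adj[i] if i < j]

    def adj_masks(self) -> list[int]:
        """Adjacency rows as integer bitmasks (bit j set iff {i, j} in E)."""
        if self._adj_mask is None:
            self._adj_mask = [
                sum(1 << j for j in a) for a in self.adj
            ]
        return self._adj_mask

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Graph(n={self.n}, m={self.m})"


def build_graph(edges: Iterable[tuple[Hashable, Hashable]],
                nodes: Iterable[Hashable] = (),
                strict: bool = False) -> Graph:
    """Build a simple graph from name pairs.

    Nodes are indexed by first appearance (extra isolated nodes may be given
    via ``nodes``).  Duplicate edges are collapsed silently; self-loops are
    skipped with a warning, or rejected when ``strict`` is set.
    """
    g = Graph()
    for name in nodes:
        g.add_node(name)
    for u, v in edges:
        if u == v:
            if strict:
                raise ValueError(f"self-loop on node {u!r}")
            log.warning("skipping self-loop on node %r", u)
            g.add_node(u)
            continue
        g.add_edge(u, v)
    return g


def density(g: Graph) -> float:
    """D(G) = m / C(n, 2), the size relative to the maximal possible size."""
    if g.n < 2:
        raise ValueError("density undefined for graphs of order < 2")
    return 2.0 * g.m / (g.n * (g.n - 1))


@dataclass(frozen=True)
class OrbitRepresentative:
    """A graphlet (connected, for catalog members) with a marked node.

    Vertices are 0..k-1; ``edges`` holds unordered index pairs (i < j).
    """

    k: int
    edges: frozenset[tuple[int, int]]
    marked: int
    _cert: tuple = field(default=None, compare=False, hash=False, repr=False)

    def __post_init__(self) -> None:
        if not (0 <= self.marked < self.k):
            raise ValueError("marked node outside vertex range")

    @property
    def e(self) -> int:
        return len(self.edges)

    def neighbours(self, v: int) -> set[int]:
        out = set()
        for a, b in self.edges:
            if a == v:
                out.add(b)
            elif b == v:
                out.add(a)
        return out

    def degree(self, v: int) -> int:
        return sum(1 for a, b in self.edges if v in (a, b))

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.k)]
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def is_connected(self) -> bool:
        if self.k == 0:
            return False
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == self.k

    def relabel(self, perm: Sequence[int]) -> "OrbitRepresentative":
        """Return the representative with vertex v renamed perm[v]."""
        edges = frozenset(
            (min(perm[a], perm[b]), max(perm[a], perm[b]))
            for a, b in self.edges
        )
        return OrbitRepresentative(self.k, edges, perm[self.marked])


# pair_rank[(i, j)] with i < j inside a k-vertex representative
def _pair_bit(i: int, j: int) -> int:
    # colexicographic rank of the pair (i < j): C(j, 2) + i
    return j * (j - 1) // 2 + i


def _edge_bits(edges: Iterable[tuple[int, int]], perm: Sequence[int]) -> int:
    bits = 0
    for a, b in edges:
        x, y = perm[a], perm[b]
        if x > y:
            x, y = y, x
        bits |= 1 << _pair_bit(x, y)
    return bits


def _marked_perms(rep: OrbitRepresentative):
    """All vertex->position maps sending the marked node to position 0."""
    others = [v for v in range(rep.k) if v != rep.marked]
    for order in permutations(range(1, rep.k)):
        perm = [0] * rep.k
        perm[rep.marked] = 0
        for v, p in zip(others, order):
            perm[v] = p
        yield perm


def canonical_certificate(rep: OrbitRepresentative) -> tuple[int, int]:
    """Canonical encoding of a marked graph: ``(k, bits)``.

    ``bits`` is the minimum, over all vertex orderings that place the marked
    node first, of the upper-triangular adjacency encoding.  Equal
    certificates <=> a marked-preserving isomorphism exists.  Brute force
    over (k-1)! orderings — intended for k <= 8.
    """
    if rep._cert is not None:
        return rep._cert
    best = None
    for perm in _marked_perms(rep):
        bits = _edge_bits(rep.edges, perm)
        if best is None or bits < best:
            best = bits
    cert = (rep.k, best if best is not None else 0)
    object.__setattr__(rep, "_cert", cert)
    return cert


def canonical_form(rep: OrbitRepresentative) -> OrbitRepresentative:
    """The representative relabelled into its certificate ordering."""
    best = None
    best_perm = None
    for perm in _marked_perms(rep):
        bits = _edge_bits(rep.edges, perm)
        if best is None or bits < best:
            best, best_perm = bits, perm
    if best_perm is None:  # k == 1
        return rep
    return rep.relabel(best_perm)


def marked_isomorphic(a: OrbitRepresentative, b: OrbitRepresentative) -> bool:
    """True iff a bijection exists preserving edges and marked -> marked."""
    if a.k != b.k or a.e != b.e:
        return False
    return canonical_certificate(a) == canonical_certificate(b)


def find_marked_isomorphism(a: OrbitRepresentative,
                            b: OrbitRepresentative) -> list[int] | None:
    """One vertex map f with f(marked(a)) = marked(b) preserving edges."""
    if a.k != b.k or a.e != b.e:
        return None
    b_edges = b.edges
    others_a = [v for v in range(a.k) if v != a.marked]
    others_b = [v for v in range(b.k) if v != b.marked]
    for image in permutations(others_b):
        f = [0] * a.k
        f[a.marked] = b.marked
        for v, w in zip(others_a, image):
            f[v] = w
        ok = True
        for x, y in a.edges:
            fx, fy = f[x], f[y]
            if (min(fx, fy), max(fx, fy)) not in b_edges:
                ok = False
                break
        if ok:
            return f
    return None


def automorphism_group(rep: OrbitRepresentative) -> list[tuple[int, ...]]:
    """All permutations fixing the marked node and preserving the edge set.

    Closed under composition and inverse; always contains the identity.
    Brute force over (k-1)! permutations.
    """
    group = []
    edges = rep.edges
    others = [v for v in range(rep.k) if v != rep.marked]
    for image in permutations(others):
        f = list(range(rep.k))
        for v, w in zip(others, image):
            f[v] = w
        ok = True
        for a, b in edges:
            fa, fb = f[a], f[b]
            if (min(fa, fb), max(fa, fb)) not in edges:
                ok = False
                break
        if ok:
            group.append(tuple(f))
    return group


def induced_marked_subgraph(g: Graph, subset: Iterable[int],
                            marked: int) -> OrbitRepresentative:
    """G[V_s, x]: the marked subgraph induced on ``subset`` (host indices).

    Vertices are relabelled to 0..|V_s|-1 following the host index order.
    The output need not be connected.
    """
    sub = sorted(set(subset))
    if marked not in sub:
        raise ValueError("marked node must belong to the subset")
    pos = {v: i for i, v in enumerate(sub)}
    edges = frozenset(
        (pos[a], pos[b])
        for a, b in combinations(sub, 2)
        if b in g.adj[a]
    )
    return OrbitRepresentative(len(sub), edges, pos[marked])


def common_neighbour_count(g: Graph, subset: Iterable[int]) -> int:
    """c(V_s): number of nodes adjacent to every member of ``subset``.

    Members of the subset never qualify (no self-loops).
    """
    it = iter(set(subset))
    try:
        first = next(it)
    except StopIteration:
        raise ValueError("common neighbours of the empty set are undefined")
    common = set(g.adj[first])
    for v in it:
        common &= g.adj[v]
    return len(common)
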