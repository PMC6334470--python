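"""Enumeration and numbering of orbit representatives, and the orbit tree.

Representatives up to a maximal order are generated once, deduplicated by
their canonical certificate, and numbered by ``(order, edge count,
certificate)``.  That ordering is edge-monotone: adding an edge to a
representative always yields one with a strictly larger index, so any
one-equation-per-orbit system built later is automatically upper
triangular.

The orbit tree links every representative to a parent by a single action —
adding a node attached by one edge, or adding one edge — and drives the
tree-walking instance search :func:`match_instances`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Iterator

import networkx as nx

from .graph import (
    Graph,
    OrbitRepresentative,
    automorphism_group,
    canonical_certificate,
    canonical_form,
    find_marked_isomorphism,
    induced_marked_subgraph,
)

__all__ = [
    "OrbitCatalog",
    "OrbitTree",
    "Instance",
    "enumerate_representatives",
    "build_orbit_tree",
    "match_instances",
]

MAX_ORDER = 8


class OrbitCatalog:
    """Ordered, duplicate-free list of orbit representatives up to an order.

    ``reps[i]`` is stored in canonical labelling (marked node = 0).
    """

    def __init__(self, max_order: int) -> None:
        self.max_order = max_order
        self.reps: list[OrbitRepresentative] = []
        self.by_order: dict[int, list[int]] = {}
        self._index_of_cert: dict[tuple, int] = {}

    def _finalize(self, reps: list[OrbitRepresentative]) -> None:
        reps.sort(key=lambda r: (r.k, r.e, canonical_certificate(r)[1]))
        self.reps = reps
        for i, r in enumerate(reps):
            self._index_of_cert[canonical_certificate(r)] = i
            self.by_order.setdefault(r.k, []).append(i)

    def index_of(self, rep: OrbitRepresentative) -> int:
        """Catalog index of the representative's isomorphism class."""
        return self._index_of_cert[canonical_certificate(rep)]

    def get(self, rep: OrbitRepresentative) -> int | None:
        return self._index_of_cert.get(canonical_certificate(rep))

    def orbits_of_order(self, k: int) -> list[int]:
        return self.by_order.get(k, [])

    def __len__(self) -> int:
        return len(self.reps)


def _connected_unlabelled_graphs(max_order: int) -> dict[int, list[frozenset]]:
    """All connected unlabelled graphs per order, as edge sets on 0..k-1.

    Order k graphs are grown from order k-1 graphs by attaching a new node
    to every non-empty subset of the old vertices (every connected graph has
    a removable non-cut vertex, so this is exhaustive).  Deduplication uses
    Weisfeiler-Lehman hash buckets with an exact isomorphism check.
    """
    out: dict[int, list[frozenset]] = {1: [frozenset()]}
    for k in range(2, max_order + 1):
        buckets: dict[str, list[tuple[frozenset, nx.Graph]]] = {}
        found: list[frozenset] = []
        for base in out[k - 1]:
            for r in range(1, k):
                for attach in combinations(range(k - 1), r):
                    edges = frozenset(base) | {(a, k - 1) for a in attach}
                    G = nx.Graph()
                    G.add_nodes_from(range(k))
                    G.add_edges_from(edges)
                    key = f"{len(edges)}:" + nx.weisfeiler_lehman_graph_hash(
                        G, iterations=3)
                    bucket = buckets.setdefault(key, [])
                    if any(nx.is_isomorphic(G, H) for _, H in bucket):
                        continue
                    bucket.append((edges, G))
                    found.append(edges)
        out[k] = found
    return out


@lru_cache(maxsize=None)
def enumerate_representatives(max_order: int) -> OrbitCatalog:
    """Complete catalog of orbit representatives of orders 1..max_order."""
    if not (1 <= max_order <= MAX_ORDER):
        raise ValueError(f"max_order must be in 1..{MAX_ORDER}")
    catalog = OrbitCatalog(max_order)
    reps: list[OrbitRepresentative] = []
    seen: set[tuple] = set()
    graphs = _connected_unlabelled_graphs(max_order)
    for k in range(1, max_order + 1):
        for edges in graphs[k]:
            for v in range(k):
                rep = OrbitRepresentative(k, edges, v)
                cert = canonical_certificate(rep)
                if cert in seen:
                    continue
                seen.add(cert)
                reps.append(canonical_form(rep))
    catalog._finalize(reps)
    return catalog


@dataclass(frozen=True)
class Arc:
    """Tree arc: apply ``action`` to the parent to obtain the child.

    ``relabel`` maps parent vertex labels to child vertex labels.
    action = ("node", new_label, attach_label): add a vertex (child label
    ``new_label``) joined to ``attach_label`` by one edge.
    action = ("edge", a, b): add the edge {a, b} (child labels).
    """

    parent: int
    child: int
    action: tuple
    relabel: tuple[int, ...]


class OrbitTree:
    """Directed spanning tree over catalog indices, rooted at the 1-node
    representative; every representative of order >= 2 has one parent."""

    def __init__(self, catalog: OrbitCatalog) -> None:
        self.catalog = catalog
        self.root = catalog.orbits_of_order(1)[0]
        self.children: dict[int, list[Arc]] = {}
        self.parent_arc: dict[int, Arc] = {}

    def add_arc(self, arc: Arc) -> None:
        self.children.setdefault(arc.parent, []).append(arc)
        self.parent_arc[arc.child] = arc


def _remove_vertex(rep: OrbitRepresentative, v: int) -> tuple[
        OrbitRepresentative, list[int]]:
    """Representative minus vertex v, plus old-label list by new label."""
    keep = [u for u in range(rep.k) if u != v]
    pos = {u: i for i, u in enumerate(keep)}
    edges = frozenset(
        (pos[a], pos[b]) for a, b in rep.edges if a != v and b != v)
    return OrbitRepresentative(rep.k - 1, edges, pos[rep.marked]), keep


def build_orbit_tree(catalog: OrbitCatalog) -> OrbitTree:
    """Attach each representative to a parent reachable by one action.

    Preference: an edge-removal parent (same vertex set, remainder
    connected) with the smallest catalog index; for trees (no removable
    edge) a node-removal parent via a non-marked degree-1 vertex.
    """
    tree = OrbitTree(catalog)
    for child_idx, child in enumerate(catalog.reps):
        if child.k == 1:
            continue
        best = None  # (parent_idx, tiebreak, arc)
        # AddEdge parent: remove one edge, stay connected
        for a, b in sorted(child.edges):
            reduced = OrbitRepresentative(
                child.k, child.edges - {(a, b)}, child.marked)
            if not reduced.is_connected():
                continue
            pidx = catalog.get(reduced)
            if pidx is None:  # pragma: no cover - catalog is complete
                continue
            f = find_marked_isomorphism(catalog.reps[pidx], reduced)
            arc = Arc(pidx, child_idx, ("edge", a, b), tuple(f))
            if best is None or (pidx, (a, b)) < best[:2]:
                best = (pidx, (a, b), arc)
        if best is None:
            # AddNode parent: remove a non-marked leaf
            for v in range(child.k):
                if v == child.marked or child.degree(v) != 1:
                    continue
                reduced, keep = _remove_vertex(child, v)
                pidx = catalog.get(reduced)
                if pidx is None:  # pragma: no cover
                    continue
                f = find_marked_isomorphism(catalog.reps[pidx], reduced)
                relabel = tuple(keep[p] for p in f)
                (attach,) = child.neighbours(v)
                arc = Arc(pidx, child_idx, ("node", v, attach), relabel)
                if best is None or (pidx, (v,)) < best[:2]:
                    best = (pidx, (v,), arc)
        if best is None:
            raise RuntimeError(
                f"no parent found for representative {child_idx}")
        tree.add_arc(best[2])
    return tree


@dataclass(frozen=True)
class Instance:
    """A found instance: host nodes aligned to representative labels."""

    nodes: tuple[int, ...]
    marked: int
    orbit: int


def match_instances(g: Graph, tree: OrbitTree, root_node: int,
                    up_to_order: int) -> Iterator[Instance]:
    """Yield every instance rooted at ``root_node`` exactly once.

    Walks the orbit tree: node arcs extend the partial assignment by a host
    neighbour of the attachment vertex, edge arcs test edge presence.  An
    assignment is emitted at a tree node only when the induced host edges
    match the representative exactly (required non-edges hold) and the
    assignment is the canonical one under the representative's
    automorphisms, so each (node set, marked) pair appears once.
    """
    if root_node not in range(g.n):
        raise ValueError("root node not in graph")
    catalog = tree.catalog
    aut_cache: dict[int, list[tuple[int, ...]]] = {}

    def emit(idx: int, assign: list[int]) -> bool:
        rep = catalog.reps[idx]
        # induced exactness: every representative non-edge absent in host
        for a, b in combinations(range(rep.k), 2):
            if (a, b) not in rep.edges and g.has_edge_idx(
                    assign[a], assign[b]):
                return False
        auts = aut_cache.get(idx)
        if auts is None:
            auts = automorphism_group(rep)
            aut_cache[idx] = auts
        tup = tuple(assign)
        for f in auts:
            if tuple(assign[f[l]] for l in range(rep.k)) < tup:
                return False
        return True

    def walk(idx: int, assign: list[int]) -> Iterator[Instance]:
        rep = catalog.reps[idx]
        if emit(idx, assign):
            yield Instance(tuple(assign), root_node, idx)
        for arc in tree.children.get(idx, []):
            child = catalog.reps[arc.child]
            if child.k > up_to_order:
                continue
            if arc.action[0] == "edge":
                _, a, b = arc.action
                new = [0] * child.k
                for pl, cl in enumerate(arc.relabel):
                    new[cl] = assign[pl]
                if g.has_edge_idx(new[a], new[b]):
                    yield from walk(arc.child, new)
            else:
                _, new_label, attach = arc.action
                new = [0] * child.k
                for pl, cl in enumerate(arc.relabel):
                    new[cl] = assign[pl]
                used = {new[cl] for cl in range(child.k) if cl != new_label}
                for w in g.adj[new[attach]]:
                    if w in used:
                        continue
                    new[new_label] = w
                    yield from walk(arc.child, list(new))

    yield from walk(tree.root, [root_node])


# ---------------------------------------------------------------------------
# plain-text serialization (catalog + tree), mirroring pre-generated
# orbit/tree files of the desktop app export format


def write_catalog(catalog: OrbitCatalog, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# orbit representatives, max order {catalog.max_order}\n")
        for i, rep in enumerate(catalog.reps):
            edges = " ".join(f"{a}-{b}" for a, b in sorted(rep.edges))
            fh.write(f"{i}\t{rep.k}\t{rep.marked}\t{edges}\n")


def write_tree(tree: OrbitTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# orbit tree arcs: parent child action relabel\n")
        for child in sorted(tree.parent_arc):
            arc = tree.parent_arc[child]
            act = ",".join(str(x) for x in arc.action)
            rel = ",".join(str(x) for x in arc.relabel)
            fh.write(f"{arc.parent}\t{arc.child}\t{act}\t{rel}\n")
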