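"""Independent ground truth: brute-force degrees and analytic expectations.

:func:`brute_force_degrees` realises the graphlet-degree definition
directly — enumerate every connected induced subgraph, classify each
(subset, member) pair by certificate — and serves as the oracle the
equation-based engine is validated against.

:func:`expected_instances_er` gives the expected number of instances of a
marked representative in a uniform exact-size ER graph, both exactly and in
the large-n approximation D^e (1-D)^(C(k,2)-e) C(n,k) S with symmetry
factor S = k!/|Aut(Ω)| (automorphisms fixing the marked node, so instances
count marked placements).  The exact form fixes the e representative edges
and the C(k,2)-e non-edges sequentially without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb, factorial

import numpy as np

from .catalog import OrbitCatalog, enumerate_representatives
from .engine import GraphletDegreeMatrix
from .graph import (
    Graph,
    OrbitRepresentative,
    automorphism_group,
    induced_marked_subgraph,
)

__all__ = [
    "ExpectedCountInputs",
    "brute_force_degrees",
    "expected_instances_er",
    "asymptotic_density_factor",
]


def _is_connected_subset(g: Graph, subset: tuple[int, ...]) -> bool:
    sub = set(subset)
    seen = {subset[0]}
    stack = [subset[0]]
    while stack:
        v = stack.pop()
        for w in g.adj[v]:
            if w in sub and w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == len(sub)


def brute_force_degrees(g: Graph, k: int,
                        catalog: OrbitCatalog | None = None
                        ) -> GraphletDegreeMatrix:
    """Degrees of all orbits of orders 2..k by exhaustive subset scan.

    Tractable for n up to ~16; every connected subset is classified once
    per member via the marked certificate.
    """
    if catalog is None:
        catalog = enumerate_representatives(k)
    n = g.n
    deg = {idx: [0] * n
           for order in range(2, k + 1)
           for idx in catalog.orbits_of_order(order)}
    # memoize certificate classification per induced edge pattern
    memo: dict[tuple[int, frozenset, int], int] = {}
    for size in range(2, k + 1):
        for subset in combinations(range(n), size):
            if not _is_connected_subset(g, subset):
                continue
            pattern = frozenset(
                (i, j)
                for i in range(size) for j in range(i + 1, size)
                if subset[j] in g.adj[subset[i]])
            for p, x in enumerate(subset):
                key = (size, pattern, p)
                idx = memo.get(key)
                if idx is None:
                    idx = catalog.index_of(
                        induced_marked_subgraph(g, subset, x))
                    memo[key] = idx
                deg[idx][x] += 1
    orbit_indices = sorted(deg)
    data = np.array([deg[i] for i in orbit_indices], dtype=np.int64).T
    if data.size == 0:
        data = np.zeros((n, len(orbit_indices)), dtype=np.int64)
    return GraphletDegreeMatrix(
        node_names=list(g.names), orbit_indices=orbit_indices, data=data)


@dataclass(frozen=True)
class ExpectedCountInputs:
    """Inputs for the ER expected-instance-count formula."""

    n: int
    m: int
    k: int
    e: int
    S: int  # symmetry factor k!/|Aut(rep)|, Aut fixing the marked node

    @classmethod
    def from_representative(cls, n: int, m: int,
                            rep: OrbitRepresentative) -> "ExpectedCountInputs":
        aut = len(automorphism_group(rep))
        s, r = divmod(factorial(rep.k), aut)
        if r:
            raise ValueError("automorphism count must divide k!")
        return cls(n=n, m=m, k=rep.k, e=rep.e, S=s)


def expected_instances_er(
        inputs: ExpectedCountInputs) -> tuple[Fraction, float]:
    """(exact, asymptotic) expected instance counts in ER(n, m).

    Exact: the probability that a fixed k-subset realises the e edges and
    the C(k,2)-e non-edges of the representative, times C(n,k)*S placements:

        prod_{i<e} (m-i)/(C(n,2)-i)
      * prod_{j<C(k,2)-e} (C(n,2)-m-j)/(C(n,2)-e-j)
      * C(n,k) * S
    """
    n, m, k, e, s = inputs.n, inputs.m, inputs.k, inputs.e, inputs.S
    pairs = comb(n, 2)
    total = comb(k, 2)
    if e > m or total - e > pairs - m:
        raise ValueError("infeasible configuration: not enough (non-)edges")
    exact = Fraction(comb(n, k) * s)
    for i in range(e):
        exact *= Fraction(m - i, pairs - i)
    for j in range(total - e):
        exact *= Fraction(pairs - m - j, pairs - e - j)
    d = m / pairs
    asymptotic = (d ** e) * ((1 - d) ** (total - e)) * comb(n, k) * s
    return exact, asymptotic


def asymptotic_density_factor(density: float, k: int, e: int) -> float:
    """D^e (1-D)^(C(k,2)-e): the density-dependent part of the asymptotic
    expectation.  The consecutive-e ratio is D/(1-D), so at D = 0.5 the
    factor equals 2^(-C(k,2)) regardless of e, below 0.5 it decreases with
    e (dense representatives are rare in sparse graphs) and above 0.5 it
    increases with e."""
    return density ** e * (1.0 - density) ** (comb(k, 2) - e)
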