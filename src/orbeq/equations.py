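"""Generation of graphlet-degree counting equations.

Removing one non-marked node ``a`` from an order-k orbit representative
(when the remainder stays connected) yields a (k-1)-representative Ω and an
argument set S = N(a), expressed in Ω's labels.  Summing, over all host
instances of Ω at a node x, the common-neighbour counts c(S') over the
Aut(Ω)-orbit A of S (each minus a constant adjustment — the common
neighbours of S' *inside* Ω) counts extensions of Ω-instances by one node,
i.e. a fixed non-negative integer combination of order-k graphlet degrees:

    sum_j  lhs_j * o_j(x)  =  sum_{instances I of Ω at x} sum_{S' in A}
                                 [ c_G(I(S')) - adj(S') ]

The LHS coefficient of orbit j is obtained by evaluating the RHS on orbit
j's own representative as host (there o_j = 1 and every other order-k
degree vanishes).  Each orbit admits several such equations — one per
structurally distinct removal — and they are all correct; the argument
count |S| equals the edge difference e(target) - e(Ω), which is what the
density-driven selection strategies key on.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Iterable

from .catalog import OrbitCatalog, enumerate_representatives
from .graph import (
    OrbitRepresentative,
    automorphism_group,
    canonical_certificate,
    find_marked_isomorphism,
)

__all__ = [
    "Decomposition",
    "Equation",
    "decompose_orbit",
    "build_equation",
    "generate_all_equations",
    "count_equation_systems",
    "format_equation",
]


@dataclass(frozen=True)
class Decomposition:
    """One single-node decomposition of an order-k orbit representative."""

    target: int                    # catalog index of the k-orbit
    removed_degree: int            # degree of the removed node in the target
    omega: int                     # catalog index of the (k-1)-representative
    argument_sets: tuple[tuple[int, ...], ...]  # Aut(omega)-orbit of S
    adjustments: tuple[int, ...]   # per argument set: c within omega

    @property
    def n_args(self) -> int:
        return len(self.argument_sets[0])

    @property
    def n_terms(self) -> int:
        return len(self.argument_sets)


@dataclass(frozen=True)
class Equation:
    """One counting identity for an order-k orbit."""

    target: int
    lhs: tuple[tuple[int, int], ...]  # (orbit index, coefficient), ascending
    omega: int
    argument_sets: tuple[tuple[int, ...], ...]
    adjustments: tuple[int, ...]

    @property
    def n_args(self) -> int:
        return len(self.argument_sets[0])

    @property
    def n_terms(self) -> int:
        return len(self.argument_sets)

    def lhs_dict(self) -> dict[int, int]:
        return dict(self.lhs)


def _adjustment(omega: OrbitRepresentative, s: tuple[int, ...]) -> int:
    """Common neighbours of the argument set inside omega itself."""
    adj = omega.adjacency()
    return sum(
        1 for w in range(omega.k)
        if w not in s and all(w in adj[v] for v in s)
    )


def _orbit_of_set(omega: OrbitRepresentative,
                  s: Iterable[int]) -> tuple[tuple[int, ...], ...]:
    """The Aut(omega)-orbit of a label set, as sorted, ordered tuples."""
    base = tuple(sorted(s))
    images = {
        tuple(sorted(f[v] for v in base))
        for f in automorphism_group(omega)
    }
    return tuple(sorted(images))


def _family_key(omega: OrbitRepresentative,
                family: tuple[tuple[int, ...], ...]) -> tuple:
    """Canonical form of an Aut-closed set family (already Aut-closed, the
    family is its own canonical form; keep a stable sorted encoding)."""
    return tuple(sorted(family))


def decompose_orbit(target: OrbitRepresentative | int,
                    catalog: OrbitCatalog) -> list[Decomposition]:
    """All deduplicated single-node decompositions of an order >= 3 orbit.

    One decomposition per (Ω, argument-set-family) class over removable
    non-marked nodes whose removal keeps the remainder connected.
    """
    if isinstance(target, int):
        target_idx = target
        rep = catalog.reps[target_idx]
    else:
        rep = target
        target_idx = catalog.index_of(rep)
    if rep.k < 3:
        raise ValueError("decomposition requires order >= 3")
    out: list[Decomposition] = []
    seen: set[tuple] = set()
    adj = rep.adjacency()
    for a in range(rep.k):
        if a == rep.marked:
            continue
        keep = [v for v in range(rep.k) if v != a]
        pos = {v: i for i, v in enumerate(keep)}
        edges = frozenset(
            (pos[x], pos[y]) for x, y in rep.edges if a not in (x, y))
        reduced = OrbitRepresentative(rep.k - 1, edges, pos[rep.marked])
        if not reduced.is_connected():
            continue
        omega_idx = catalog.get(reduced)
        omega = catalog.reps[omega_idx]
        # express S = N(a) in the catalog representative's labels
        f = find_marked_isomorphism(reduced, omega)
        s = tuple(sorted(f[pos[v]] for v in adj[a]))
        family = _orbit_of_set(omega, s)
        key = (omega_idx, _family_key(omega, family))
        if key in seen:
            continue
        seen.add(key)
        out.append(Decomposition(
            target=target_idx,
            removed_degree=len(s),
            omega=omega_idx,
            argument_sets=family,
            adjustments=tuple(_adjustment(omega, sp) for sp in family),
        ))
    if not out:
        raise RuntimeError(
            f"no decomposition found for orbit {target_idx}")
    out.sort(key=lambda d: (d.omega, d.argument_sets))
    return out


@lru_cache(maxsize=None)
def _host_reductions(max_order: int, host_idx: int) -> tuple:
    """Single-node reductions of a catalog representative: per non-marked
    vertex, the kept labels, the reduced representative and its omega
    index (None when disconnected)."""
    catalog = enumerate_representatives(max_order)
    host = catalog.reps[host_idx]
    k = host.k
    out = []
    for removed in range(k):
        if removed == host.marked:
            continue
        keep = tuple(v for v in range(k) if v != removed)
        pos = {v: i for i, v in enumerate(keep)}
        edges = frozenset(
            (pos[x], pos[y]) for x, y in host.edges
            if removed not in (x, y))
        sub = OrbitRepresentative(k - 1, edges, pos[host.marked])
        out.append((removed, keep, sub, catalog.get(sub)))
    return tuple(out)


def _rhs_on_host(d: Decomposition, catalog: OrbitCatalog,
                 host_idx: int) -> int:
    """Evaluate the RHS functional on a k-node representative as host."""
    omega = catalog.reps[d.omega]
    host = catalog.reps[host_idx]
    adj = host.adjacency()
    total = 0
    for removed, keep, sub, sub_idx in _host_reductions(
            catalog.max_order, host_idx):
        if sub_idx != d.omega:
            continue
        f = find_marked_isomorphism(omega, sub)
        # c_host(f(S')) - adj(S') counts common neighbours outside the
        # instance; here the only outside vertex is ``removed``.
        for sp in d.argument_sets:
            if all(keep[f[v]] in adj[removed] for v in sp):
                total += 1
    return total


def build_equation(d: Decomposition, catalog: OrbitCatalog) -> Equation:
    """LHS coefficients by RHS evaluation on every same-order orbit."""
    k = catalog.reps[d.target].k
    lhs = []
    for j in catalog.orbits_of_order(k):
        coeff = _rhs_on_host(d, catalog, j)
        if coeff:
            lhs.append((j, coeff))
    eq = Equation(
        target=d.target,
        lhs=tuple(lhs),
        omega=d.omega,
        argument_sets=d.argument_sets,
        adjustments=d.adjustments,
    )
    keys = [j for j, _ in lhs]
    if d.target not in keys or min(keys) != d.target:
        raise RuntimeError(
            f"equation for orbit {d.target} is not triangular: {lhs}")
    return eq


@lru_cache(maxsize=None)
def _equations_cached(k: int, max_order: int) -> dict[int, tuple[Equation, ...]]:
    catalog = enumerate_representatives(max_order)
    out = {}
    for idx in catalog.orbits_of_order(k):
        out[idx] = tuple(
            build_equation(d, catalog)
            for d in decompose_orbit(idx, catalog)
        )
    return out


def generate_all_equations(
        k: int, catalog: OrbitCatalog) -> dict[int, list[Equation]]:
    """Full candidate lists per order-k orbit, sorted by (omega, family).

    Only equations whose terms fit the common-neighbour table are kept,
    i.e. argument sets of at most k-2 nodes.  The complete graphlet K_k is
    the single orbit this leaves without a candidate (its unique
    decomposition needs k-1 arguments); it is counted directly by the
    engine and carries no equation.
    """
    if k < 3:
        raise ValueError("equations require k >= 3")
    if k > catalog.max_order:
        raise ValueError("catalog does not cover the requested order")
    cached = _equations_cached(k, catalog.max_order)
    out = {}
    for idx, eqs in cached.items():
        usable = [eq for eq in eqs if eq.n_args <= k - 2]
        if usable:
            out[idx] = usable
    return out


def count_equation_systems(k: int, catalog: OrbitCatalog) -> int:
    """Number of maximal linearly independent systems for order k: the
    exact product of per-orbit usable candidate counts (terms of at most
    k-2 arguments; the directly counted K_k contributes no factor)."""
    total = 1
    for idx in catalog.orbits_of_order(k):
        usable = [d for d in decompose_orbit(idx, catalog)
                  if d.n_args <= k - 2]
        total *= max(len(usable), 1)
    return total


def scientific(x: int, digits: int = 2) -> str:
    """Scientific-notation rendering of an exact integer, e.g. ``3.5e+182``."""
    from decimal import Decimal
    return f"{Decimal(x):.{digits - 1}e}"


def format_equation(eq: Equation, tex: bool = False) -> str:
    """Plain-text / TeX-like rendering of one counting identity."""
    if tex:
        lhs = " + ".join(
            (f"{c}" if c > 1 else "") + f"o_{{{j}}}(x)" for j, c in eq.lhs)
        terms = " + ".join(
            f"[c({','.join(map(str, sp))}) - {adj}]" if adj else
            f"c({','.join(map(str, sp))})"
            for sp, adj in zip(eq.argument_sets, eq.adjustments))
        return (f"{lhs} = \\sum_{{\\Omega_{{{eq.omega}}}\\ni x}} {terms}")
    lhs = " + ".join(
        (f"{c}*" if c > 1 else "") + f"o_{j}(x)" for j, c in eq.lhs)
    terms = " + ".join(
        f"[c({','.join(map(str, sp))}) - {adj}]" if adj else
        f"c({','.join(map(str, sp))})"
        for sp, adj in zip(eq.argument_sets, eq.adjustments))
    return f"{lhs} = sum over Omega<{eq.omega}> instances of {terms}"
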