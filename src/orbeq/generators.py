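"""Seeded random-graph generators: ER, BA and geometric.

These are the three test-graph families used to probe how equation
selection interacts with density: Erdős-Rényi graphs of exact size,
Barabási-Albert preferential-attachment graphs grown from a complete seed
graph, and random geometric graphs in a unit cube or torus.  All are
deterministic per seed and return simple graphs of exact order.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

from .graph import Graph

log = logging.getLogger(__name__)

__all__ = ["GeoConfig", "generate_er", "generate_ba", "generate_geo"]


def _empty_graph(n: int) -> Graph:
    g = Graph()
    for v in range(n):
        g.add_node(v)
    return g


def generate_er(n: int, m: int, seed: int) -> Graph:
    """Uniform graph with exactly n nodes and m edges.

    Edges are added one by one, drawing a uniform random pair and rejecting
    pairs already connected — equivalent to a uniform m-subset of pairs.
    """
    if m > comb(n, 2):
        raise ValueError(f"m={m} exceeds C({n},2)={comb(n, 2)}")
    rng = random.Random(seed)
    g = _empty_graph(n)
    added = 0
    while added < m:
        i = rng.randrange(n)
        j = rng.randrange(n)
        if i == j:
            continue
        if g.add_edge(i, j):
            added += 1
    return g


def generate_ba(n: int, delta: int, seed: int) -> Graph:
    """Preferential attachment from a complete seed graph K_delta.

    Each new node connects to ``delta`` distinct existing nodes, drawn
    sequentially with probability proportional to current degree
    (renormalised over not-yet-chosen nodes; uniform when all weights are
    zero).  Size is exactly C(delta, 2) + (n - delta) * delta.
    """
    if not (1 <= delta <= n):
        raise ValueError("delta must satisfy 1 <= delta <= n")
    rng = random.Random(seed)
    g = _empty_graph(n)
    degree = [0] * n
    for i, j in combinations(range(delta), 2):
        g.add_edge(i, j)
        degree[i] += 1
        degree[j] += 1
    for new in range(delta, n):
        chosen: list[int] = []
        available = list(range(new))
        for _ in range(delta):
            total = sum(degree[v] for v in available)
            if total == 0:
                pick = available[rng.randrange(len(available))]
            else:
                r = rng.random() * total
                acc = 0.0
                pick = available[-1]
                for v in available:
                    acc += degree[v]
                    if r < acc:
                        pick = v
                        break
            available.remove(pick)
            chosen.append(pick)
        for v in chosen:
            g.add_edge(new, v)
            degree[new] += 1
            degree[v] += 1
    return g


@dataclass(frozen=True)
class GeoConfig:
    """Geometric-graph parameters: D-dimensional unit cube (or torus),
    either a fixed radius threshold r or an exact target size m."""

    dims: int = 3
    radius: float | None = None
    m: int | None = None
    topology: str = "cube"

    def __post_init__(self) -> None:
        if self.dims < 1:
            raise ValueError("dims must be >= 1")
        if self.topology not in ("cube", "torus"):
            raise ValueError("topology must be 'cube' or 'torus'")
        if (self.radius is None) == (self.m is None):
            raise ValueError("specify exactly one of radius or target size m")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be positive")


def generate_geo(n: int, config: GeoConfig, seed: int) -> Graph:
    """n uniform points in the unit D-cube; nodes within the threshold
    distance are connected.  In target-size mode the threshold is the m-th
    smallest pairwise distance, so the size is exactly m."""
    rng = random.Random(seed)
    pts = [[rng.random() for _ in range(config.dims)] for _ in range(n)]
    torus = config.topology == "torus"

    def dist2(a: list[float], b: list[float]) -> float:
        s = 0.0
        for x, y in zip(a, b):
            d = abs(x - y)
            if torus:
                d = min(d, 1.0 - d)
            s += d * d
        return s

    g = _empty_graph(n)
    if config.radius is not None:
        r2 = config.radius * config.radius
        for i, j in combinations(range(n), 2):
            if dist2(pts[i], pts[j]) <= r2:
                g.add_edge(i, j)
        return g
    m = config.m
    if m > comb(n, 2):
        raise ValueError(f"m={m} exceeds C({n},2)={comb(n, 2)}")
    ranked = sorted(
        ((dist2(pts[i], pts[j]), i, j) for i, j in combinations(range(n), 2)))
    for _, i, j in ranked[:m]:
        g.add_edge(i, j)
    return g


def graph_for_density(kind: str, n: int, target_density: float,
                      seed: int, geo_dims: int = 3,
                      geo_topology: str = "torus") -> Graph:
    """Density-controlled instance of one family.

    ER and GEO hit the target size exactly (GEO via rank thresholding); BA
    uses the delta whose closed-form size is nearest the target.
    """
    pairs = comb(n, 2)
    m = round(target_density * pairs)
    kind = kind.upper()
    if kind == "ER":
        return generate_er(n, m, seed)
    if kind == "GEO":
        return generate_geo(
            n, GeoConfig(dims=geo_dims, m=m, topology=geo_topology), seed)
    if kind == "BA":
        best = min(
            range(1, n + 1),
            key=lambda d: abs(comb(d, 2) + (n - d) * d - m))
        achieved = comb(best, 2) + (n - best) * best
        if achieved != m:
            log.info(
                "BA delta=%d gives size %d (target %d)", best, achieved, m)
        return generate_ba(n, best, seed)
    raise ValueError(f"unknown graph family {kind!r}")


def max_distance(config: GeoConfig) -> float:
    """Diameter of the metric: sqrt(D) on the cube, sqrt(D)/2 on the torus."""
    d = sqrt(config.dims)
    return d / 2 if config.topology == "torus" else d
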