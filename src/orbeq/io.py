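"""Edge-list input, tab-separated output, and the benchmark harness."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import GraphletDegreeMatrix, RunStats, count_orbits
from .generators import graph_for_density
from .graph import Graph, build_graph

log = logging.getLogger(__name__)

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "write_degrees",
    "read_degrees",
    "write_stats",
    "BenchmarkConfig",
    "run_benchmark",
]


class EdgeListError(ValueError):
    """Malformed edge-list input; carries the offending line number."""


def read_edge_list(path: str, strict: bool = False) -> Graph:
    """Two whitespace-separated node names per line; '#' starts a comment."""
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise EdgeListError(
                    f"{path}:{lineno}: expected two node names, got "
                    f"{len(tokens)}: {line!r}")
            edges.append((tokens[0], tokens[1]))
    return build_graph(edges, strict=strict)


def write_edge_list(g: Graph, path: str) -> None:
    with open(path, "w") as fh:
        for i, j in g.edges_idx():
            fh.write(f"{g.names[i]}\t{g.names[j]}\n")


def write_degrees(matrix: GraphletDegreeMatrix, path: str,
                  header: bool = False,
                  nodes: Sequence | None = None) -> None:
    """One line per node: name, then graphlet degrees in ascending orbit
    index, tab-separated.  Optional header line lists the orbit indices."""
    keep = None
    if nodes is not None:
        wanted = set(str(x) for x in nodes)
        keep = [i for i, name in enumerate(matrix.node_names)
                if str(name) in wanted]
    with open(path, "w") as fh:
        if header:
            fh.write("node\t" + "\t".join(
                str(i) for i in matrix.orbit_indices) + "\n")
        rows = range(len(matrix.node_names)) if keep is None else keep
        for i in rows:
            counts = "\t".join(str(int(x)) for x in matrix.data[i])
            fh.write(f"{matrix.node_names[i]}\t{counts}\n")


def read_degrees(path: str,
                 orbit_indices: Sequence[int] | None = None,
                 header: bool = False) -> GraphletDegreeMatrix:
    names, rows = [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if header:
        orbit_indices = [int(x) for x in lines[0].split("\t")[1:]]
        lines = lines[1:]
    for line in lines:
        parts = line.split("\t")
        names.append(parts[0])
        rows.append([int(x) for x in parts[1:]])
    data = np.array(rows, dtype=np.int64)
    if orbit_indices is None:
        orbit_indices = list(range(data.shape[1]))
    return GraphletDegreeMatrix(
        node_names=names, orbit_indices=list(orbit_indices), data=data)


def write_stats(stats: RunStats, path: str,
                include_times: bool = False) -> None:
    """Structured key-value text, one ``key<TAB>value`` per line.

    Wall times are informational and non-reproducible, so they are left
    out by default: identical config and seeds then give byte-identical
    stats files."""
    with open(path, "w") as fh:
        for key in ("k", "n", "m", "density", "strategy",
                    "resolved_strategy", "seed", "lookups", "intersections"):
            fh.write(f"{key}\t{getattr(stats, key)}\n")
        if include_times:
            for phase, seconds in stats.times.items():
                fh.write(f"time_{phase}\t{seconds:.6f}\n")


@dataclass(frozen=True)
class BenchmarkConfig:
    """Grid of runs: families x orders x densities x strategies x reps."""

    families: tuple[str, ...] = ("ER",)
    orders: tuple[int, ...] = (50,)
    densities: tuple[float, ...] = (0.2, 0.9)
    strategies: tuple[str, ...] = ("fewest_args", "most_args")
    repetitions: int = 5
    k: int = 5
    base_seed: int = 0
    geo_dims: int = 3
    geo_topology: str = "torus"
    extras: dict = field(default_factory=dict)


def run_benchmark(config: BenchmarkConfig) -> pd.DataFrame:
    """One record per run: family, n, density, strategy, repetition,
    seconds, lookups, intersections.  Graph seeds depend on (family, n,
    density, repetition) only, so every strategy sees the same graphs."""
    records = []
    for family in config.families:
        for n in config.orders:
            for dens in config.densities:
                for rep in range(config.repetitions):
                    seed = (config.base_seed
                            + 1009 * rep
                            + round(1e4 * dens)
                            + 131071 * n) % (2 ** 31)
                    try:
                        g = graph_for_density(
                            family, n, dens, seed,
                            geo_dims=config.geo_dims,
                            geo_topology=config.geo_topology)
                    except ValueError as exc:
                        log.warning(
                            "skipping %s n=%d density=%.2f: %s",
                            family, n, dens, exc)
                        continue
                    for strategy in config.strategies:
                        t0 = time.perf_counter()
                        _, stats = count_orbits(
                            g, config.k, strategy=strategy, seed=seed)
                        seconds = time.perf_counter() - t0
                        records.append({
                            "family": family,
                            "n": n,
                            "density": dens,
                            "achieved_density": stats.density,
                            "strategy": strategy,
                            "repetition": rep,
                            "seconds": seconds,
                            "lookups": stats.lookups,
                            "intersections": stats.intersections,
                        })
    return pd.DataFrame.from_records(records)
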