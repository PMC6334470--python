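"""Choosing one counting equation per orbit.

All candidate equations are correct; only the cost of filling in their
right-hand sides differs.  The strategies mirror the properties that can be
read off an equation without seeing the host graph: the number of explicit
RHS terms |A| and the number of arguments per term |S|.  The automatic rule
keys on graph density: sparse graphs favour few arguments (the RHS
representative is then dense, hence rare), dense graphs favour many.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .equations import Equation

__all__ = [
    "STRATEGIES",
    "EquationSystem",
    "resolve_auto",
    "select_equations",
]

STRATEGIES = (
    "first",
    "random",
    "fewest_terms",
    "most_terms",
    "fewest_args",
    "most_args",
    "auto",
)

#: density at and above which the automatic rule switches to most_args
AUTO_DENSITY_THRESHOLD = 0.7


@dataclass(frozen=True)
class EquationSystem:
    """One equation per order-k orbit, in descending target index (upper
    triangular in the catalog numbering, solvable by back-substitution)."""

    equations: tuple[Equation, ...]
    strategy: str
    seed: int | None = field(default=None)

    def by_target(self) -> dict[int, Equation]:
        return {eq.target: eq for eq in self.equations}


def _normalize(strategy: str) -> str:
    s = strategy.replace("-", "_")
    if s not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    return s


def resolve_auto(density: float) -> str:
    """Density below the 0.7 threshold -> fewest_args, else most_args."""
    if not (0.0 <= density <= 1.0):
        raise ValueError("density must lie in [0, 1]")
    return "fewest_args" if density < AUTO_DENSITY_THRESHOLD else "most_args"


_KEYS = {
    # ties: prefer fewer terms/arguments, then the smaller omega index —
    # fewer terms or arguments never increases the lookup count
    "fewest_args": lambda e: (e.n_args, e.n_terms, e.omega),
    "most_args": lambda e: (-e.n_args, e.n_terms, e.omega),
    "fewest_terms": lambda e: (e.n_terms, e.n_args, e.omega),
    "most_terms": lambda e: (-e.n_terms, e.n_args, e.omega),
}


def select_equations(candidates: dict[int, list[Equation]],
                     strategy: str,
                     seed: int | None = None) -> EquationSystem:
    """Pick one equation per orbit; deterministic given (strategy, seed).

    ``auto`` must be resolved against a graph density beforehand.
    """
    strategy = _normalize(strategy)
    if strategy == "auto":
        raise ValueError("resolve 'auto' against a density before selecting")
    if strategy == "random" and seed is None:
        raise ValueError("the random strategy requires an explicit seed")
    chosen: list[Equation] = []
    rng = random.Random(seed) if strategy == "random" else None
    for target in sorted(candidates):
        pool = candidates[target]
        if not pool:
            raise ValueError(f"no candidate equations for orbit {target}")
        if strategy == "first":
            pick = pool[0]  # candidates are sorted by ascending omega index
        elif strategy == "random":
            pick = pool[rng.randrange(len(pool))]
        else:
            pick = min(pool, key=_KEYS[strategy])
        chosen.append(pick)
    chosen.sort(key=lambda e: -e.target)
    return EquationSystem(tuple(chosen), strategy, seed)
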