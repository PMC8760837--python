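"""Exact-distance oracle, exhaustive statistics and structure fixtures.

The oracle computes true transposition distances by breadth-first search
from the identity over all block transpositions, which is feasible for
small genomes and is what the approximation solver is validated against.
The fixture builders realize chromosomes whose residuals contain prescribed
components (interleaving pairs, necklaces, the bad oriented 5-cycle, ...),
which is how the structural guarantees are exercised without enumerating
the enormous configuration case tables.
"""

from __future__ import annotations

import itertools
import math
import random
from collections import Counter, deque
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterator, Optional, Sequence

from .perm_core import (
    ChromosomeCycle,
    Mapping,
    ValidationError,
    chromosome_from_residual,
    lower_bound,
    upper_bound,
)
from .residual_structure import (
    ComponentKind,
    classify_bad_small_component,
    components_of,
)

#: BFS over S_n stores every permutation; beyond this the table no longer
#: fits comfortably in memory — use the solver and the analytic bounds.
MAX_ORACLE_N = 11


def truncate(value: float, digits: int = 4) -> float:
    """Truncate (not round) to ``digits`` decimal places."""
    scale = 10**digits
    return math.floor(value * scale) / scale


@lru_cache(maxsize=4)
def _distance_map(n: int) -> dict[tuple[int, ...], int]:
    """Distance from the identity for every permutation of size ``n``.

    Block transpositions are their own inverses as a *set* of generators,
    so BFS layers from the identity are exact distances.
    """
    ident = tuple(range(1, n + 1))
    gens = [
        (i, j, k)
        for i in range(n + 1)
        for j in range(i + 1, n + 1)
        for k in range(j + 1, n + 1)
    ]
    dist = {ident: 0}
    queue = deque([ident])
    while queue:
        p = queue.popleft()
        d = dist[p] + 1
        for i, j, k in gens:
            q = p[:i] + p[j:k] + p[i:j] + p[k:]
            if q not in dist:
                dist[q] = d
                queue.append(q)
    return dist


def exact_distance(p: Sequence[int]) -> int:
    """Minimum number of transpositions sorting ``p`` (exhaustive BFS)."""
    p = tuple(p)
    n = len(p)
    if n > MAX_ORACLE_N:
        raise ValidationError(
            f"exact distances are tabulated only for n <= {MAX_ORACLE_N}; "
            "use the solver and the lower/upper bounds for longer genomes"
        )
    ChromosomeCycle.from_one_line(p)  # validate
    return _distance_map(n)[p]


@dataclass(frozen=True)
class DistanceTable:
    """Exact distances for all of S_n, with summary statistics."""

    n: int
    histogram: tuple[tuple[int, int], ...]  # (distance, count)

    @property
    def diameter(self) -> int:
        return max(d for d, _ in self.histogram)

    @property
    def average_distance(self) -> float:
        """Mean exact distance, averaged over the n!-1 non-identity
        permutations and truncated to 4 decimals."""
        total = sum(d * c for d, c in self.histogram)
        return truncate(total / (math.factorial(self.n) - 1))


def exhaustive_stats(n: int) -> DistanceTable:
    """Exact distance table over all of S_n (2 <= n <= 9)."""
    if not 2 <= n <= 9:
        raise ValidationError("exhaustive statistics supported for 2 <= n <= 9")
    hist = Counter(_distance_map(n).values())
    return DistanceTable(n, tuple(sorted(hist.items())))


@dataclass(frozen=True)
class AlgorithmStats:
    """Solver-vs-oracle summary over all of S_n (truncated to 4 decimals)."""

    n: int
    max_ratio: float
    avg_ratio: float
    avg_distance: float
    pct_equal: float
    max_distance: int


def algorithm_stats(
    n: int, solver: Callable[[Sequence[int]], "object"]
) -> AlgorithmStats:
    """Run ``solver`` on every permutation of S_n and compare with the oracle.

    ``solver`` maps a one-line permutation to an object with a ``distance``
    attribute (a solve report).  Averages follow the oracle convention:
    sums divided by n!-1.
    """
    dist = _distance_map(n)
    worst = 0.0
    ratio_sum = 0.0
    dist_sum = 0
    equal = 0
    max_d = 0
    count = 0
    for p in itertools.permutations(range(1, n + 1)):
        exact = dist[p]
        if exact == 0:
            continue
        count += 1
        t = solver(p).distance
        if t < exact:
            raise AssertionError(f"solver undercut the exact distance on {p}")
        ratio = t / exact
        worst = max(worst, ratio)
        ratio_sum += ratio
        dist_sum += t
        max_d = max(max_d, t)
        equal += t == exact
    return AlgorithmStats(
        n=n,
        max_ratio=truncate(worst),
        avg_ratio=truncate(ratio_sum / count),
        avg_distance=truncate(dist_sum / count),
        pct_equal=truncate(100.0 * equal / count, 2),
        max_distance=max_d,
    )


def random_permutations(n: int, count: int, seed: int) -> Iterator[tuple[int, ...]]:
    """Uniform random one-line permutations, reproducible from ``seed``."""
    if n < 1 or count < 0:
        raise ValidationError("need n >= 1 and count >= 0")
    rng = random.Random(seed)
    base = list(range(1, n + 1))
    for _ in range(count):
        rng.shuffle(base)
        yield tuple(base)


def bound_ratio_harness(
    sizes: Sequence[int],
    count: int,
    seed: int,
    solver: Callable[[Sequence[int]], "object"],
) -> list[dict]:
    """Solver distance vs the 3-norm lower bound on random long genomes.

    For genomes too long for the oracle the only available reference is the
    lower bound, so the reported figure is a *bound ratio* — an upper bound
    on the true approximation ratio, not the ratio itself.
    """
    rows = []
    for n in sizes:
        worst = 0.0
        total = 0.0
        for p in random_permutations(n, count, seed + n):
            rep = solver(p)
            lb = max(rep.lower_bound, 1)
            ratio = rep.distance / lb
            worst = max(worst, ratio)
            total += ratio
        rows.append(
            {
                "n": n,
                "count": count,
                "max_bound_ratio": truncate(worst),
                "avg_bound_ratio": truncate(total / max(count, 1)),
            }
        )
    return rows


# ---------------------------------------------------------------------------
# Structure fixtures
# ---------------------------------------------------------------------------

#: Residual-cycle patterns realizing each bad small component on its own
#: block of symbols.  Each was found by exhaustive/backtracking search over
#: chromosome circular orders and is re-validated by the structural
#: classifiers whenever a fixture is built.
COMPONENT_PATTERNS: dict[ComponentKind, tuple[tuple[int, ...], ...]] = {
    ComponentKind.BAD_ORIENTED_5CYCLE: ((0, 2, 4, 1, 3),),
    ComponentKind.UNORIENTED_INTERLEAVING_PAIR: ((0, 2, 4), (1, 3, 5)),
    ComponentKind.NECKLACE_4: ((0, 2, 10), (1, 3, 5), (4, 6, 8), (7, 9, 11)),
    ComponentKind.NECKLACE_5: (
        (0, 2, 8),
        (1, 3, 5),
        (4, 10, 7),
        (6, 12, 14),
        (9, 11, 13),
    ),
    ComponentKind.NECKLACE_6: (
        (0, 2, 6),
        (1, 3, 15),
        (4, 11, 13),
        (5, 7, 9),
        (8, 10, 17),
        (12, 14, 16),
    ),
    ComponentKind.TWISTED_NECKLACE_4: (
        (0, 2, 7),
        (1, 3, 5),
        (4, 9, 11),
        (6, 8, 10),
    ),
}


def _pattern_width(cycles: Sequence[Sequence[int]]) -> int:
    return max(max(c) for c in cycles) + 1


def fixture_from_component_spec(
    kind_or_cycles: "ComponentKind | Sequence[Sequence[int]]",
    n: Optional[int] = None,
) -> ChromosomeCycle:
    """A chromosome whose residual realizes the requested component(s).

    Accepts either a :class:`ComponentKind` with a stored pattern, or
    explicit residual cycles (with ``n`` the genome length).  The result is
    validated: for a known kind, the residual must consist of exactly one
    component classified as that kind.
    """
    if isinstance(kind_or_cycles, ComponentKind):
        kind = kind_or_cycles
        if kind not in COMPONENT_PATTERNS:
            raise ValidationError(f"no stored pattern for {kind}")
        cycles = COMPONENT_PATTERNS[kind]
        width = _pattern_width(cycles)
        sigma = Mapping.from_cycles(cycles, width)
        pi_bar = chromosome_from_residual(sigma, width - 1)
        comps = components_of(pi_bar)
        if len(comps) != 1 or classify_bad_small_component(comps[0]) != kind:
            raise ValidationError(f"stored pattern no longer classifies as {kind}")
        return pi_bar
    cycles = [tuple(c) for c in kind_or_cycles]
    if n is None:
        n = _pattern_width(cycles) - 1
    sigma = Mapping.from_cycles(cycles, n + 1)
    return chromosome_from_residual(sigma, n)


def chromosome_with_components(kinds: Sequence[ComponentKind]) -> ChromosomeCycle:
    """Stack several component patterns on disjoint symbol blocks.

    Blocks occupy consecutive symbol ranges; the chromosome walk crosses
    block boundaries exactly once per block, which keeps the product a
    single cycle for the stored patterns.  Classification of every
    component is re-verified on the assembled chromosome.
    """
    cycles: list[tuple[int, ...]] = []
    offset = 0
    for kind in kinds:
        pattern = COMPONENT_PATTERNS[kind]
        for cyc in pattern:
            cycles.append(tuple(s + offset for s in cyc))
        offset += _pattern_width(pattern)
    sigma = Mapping.from_cycles(cycles, offset)
    pi_bar = chromosome_from_residual(sigma, offset - 1)
    comps = components_of(pi_bar)
    got = sorted(classify_bad_small_component(c).value for c in comps)
    want = sorted(k.value for k in kinds)
    if got != want:
        raise ValidationError(
            f"stacked fixture classified as {got}, expected {want}"
        )
    return pi_bar


def oracle_sweep(n: int) -> Iterator[tuple[tuple[int, ...], int]]:
    """All non-identity permutations of size ``n`` with exact distances."""
    dist = _distance_map(n)
    for p in itertools.permutations(range(1, n + 1)):
        if dist[p]:
            yield p, dist[p]
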