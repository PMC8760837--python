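"""Structural analysis of the residual permutation.

The disjoint cycles of the residual ``iota_bar * pi_bar**-1`` carry all the
information needed to pick productive transpositions: whether a cycle is
*oriented* (some triplet occurs in the chromosome in a different cyclic order
than in the cycle, which is what enables a 2-move), how cycles *intersect* or
*interleave* around the chromosome, and how they group into *components*.
Configurations — disjoint products of cycle segments — with their *open
gates* bound the search space in which an 11/8-sequence is guaranteed to
exist.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from functools import cached_property
from typing import Iterator, Sequence

from .perm_core import (
    ChromosomeCycle,
    Mapping,
    ThreeCycle,
    ValidationError,
    residual,
)

# ---------------------------------------------------------------------------
# Cyclic-order primitives
# ---------------------------------------------------------------------------


def cyclic_order(
    a: int, b: int, c: int, reference: ChromosomeCycle, in_inverse: bool = False
) -> bool:
    """True iff, reading from ``a``, ``b`` precedes ``c``.

    Reads the chromosome cycle forward, or backwards when ``in_inverse`` is
    set (the inverse cycle is the same circle traversed the other way).
    """
    if in_inverse:
        b, c = c, b
    return reference.in_cyclic_order(a, b, c)


def is_oriented_triplet(a: int, b: int, c: int, reference: ChromosomeCycle) -> bool:
    """Oriented triplet test for ``(a, b, c)`` listed in residual-cycle order.

    The triplet is oriented when its cyclic order in the inverse chromosome
    differs from ``(a, b, c)`` — equivalently, when the 3-cycle ``(a b c)``
    is applicable on the chromosome itself.
    """
    return reference.in_cyclic_order(a, b, c)


def is_oriented(symbols: Sequence[int], reference: ChromosomeCycle) -> bool:
    """Whether a cycle/segment (symbols in cycle order) has an oriented triplet."""
    k = len(symbols)
    if k < 3:
        return False
    for i, j, l in itertools.combinations(range(k), 3):
        if is_oriented_triplet(symbols[i], symbols[j], symbols[l], reference):
            return True
    return False


def _alternate(pair1, pair2, reference: ChromosomeCycle) -> bool:
    """Do the two symbol pairs separate each other around the chromosome circle?

    Alternation is independent of reading direction, so the forward circle is
    used even though the definition is usually stated on the inverse.
    """
    a, b = pair1
    d, e = pair2
    if {a, b} & {d, e}:
        return False
    m = len(reference.symbols)
    pa = reference.position(a)
    rb = (reference.position(b) - pa) % m
    rd = (reference.position(d) - pa) % m
    re = (reference.position(e) - pa) % m
    return (rd < rb) != (re < rb)


# ---------------------------------------------------------------------------
# Segments and configurations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """A consecutive run of a residual cycle, itself treated as a cycle.

    ``symbols`` are in the cyclic order of the parent cycle; ``parent`` is the
    full parent cycle (canonical rotation).  A whole cycle is a segment of
    itself.
    """

    symbols: tuple[int, ...]
    parent: tuple[int, ...]

    def __post_init__(self):
        if len(self.symbols) < 2:
            raise ValidationError("a segment has at least 2 symbols")
        k = len(self.parent)
        start = self.parent.index(self.symbols[0])
        run = tuple(self.parent[(start + i) % k] for i in range(len(self.symbols)))
        if run != self.symbols:
            raise ValidationError(
                f"{self.symbols} is not a consecutive run of parent {self.parent}"
            )

    def __len__(self) -> int:
        return len(self.symbols)

    def pairs(self) -> tuple[tuple[int, int], ...]:
        """Consecutive pairs of the segment-as-cycle (wrap-around included)."""
        s = self.symbols
        return tuple((s[i], s[(i + 1) % len(s)]) for i in range(len(s)))

    def triplets(self) -> tuple[tuple[int, int, int], ...]:
        s = self.symbols
        if len(s) < 3:
            return ()
        return tuple(
            (s[i], s[(i + 1) % len(s)], s[(i + 2) % len(s)]) for i in range(len(s))
        )

    def __str__(self) -> str:
        return "(" + " ".join(map(str, self.symbols)) + ")"


def segment_of(cycle: Sequence[int]) -> Segment:
    """The whole-cycle segment (canonical rotation: smallest symbol first)."""
    cyc = tuple(cycle)
    j = cyc.index(min(cyc))
    cyc = cyc[j:] + cyc[:j]
    return Segment(cyc, cyc)


def intersects(s1: Segment, s2: Segment, reference: ChromosomeCycle) -> bool:
    """Some consecutive pair of each alternates around the chromosome."""
    return any(
        _alternate(p1, p2, reference) for p1 in s1.pairs() for p2 in s2.pairs()
    )


def interleaves(s1: Segment, s2: Segment, reference: ChromosomeCycle) -> bool:
    """Consecutive triplets ``(a,b,c)`` and ``(d,e,f)`` occur fully alternated
    ``(a..e..b..f..c..d..)`` around the inverse chromosome."""
    m = len(reference.symbols)
    for a, b, c in s1.triplets():
        pa = reference.position(a)
        # inverse-circle rank: reading backwards from a
        rank = lambda x: (pa - reference.position(x)) % m
        rb, rc = rank(b), rank(c)
        if not rb < rc:
            continue
        for d, e, f in s2.triplets():
            rd, re, rf = rank(d), rank(e), rank(f)
            if re < rb < rf < rc < rd:
                return True
    return False


class Configuration:
    """A disjoint product of segments of residual cycles.

    At most one segment per residual cycle.  The 3-norm of the product
    decides *small* (norm <= 8) versus *big*; the open-gate structure decides
    *full*.  ``reference`` supplies the cyclic order all queries read.
    """

    def __init__(self, segments: Sequence[Segment], reference: ChromosomeCycle):
        segs = tuple(segments)
        parents = [s.parent for s in segs]
        if len(set(parents)) != len(parents):
            raise ValidationError("at most one segment per residual cycle")
        support: set[int] = set()
        for s in segs:
            if support & set(s.symbols):
                raise ValidationError("segments must be pairwise disjoint")
            support |= set(s.symbols)
        self.segments = tuple(
            sorted(segs, key=lambda s: min(s.symbols))
        )
        self.reference = reference
        self.support = frozenset(support)

    @cached_property
    def norm(self) -> int:
        """3-norm of the product of the segment cycles."""
        total = sum(len(s) for s in self.segments)
        n_odd = sum(1 for s in self.segments if len(s) % 2 == 1)
        if (total - n_odd) % 2:
            raise ValidationError("configuration permutation is odd; norm undefined")
        return (total - n_odd) // 2

    @property
    def is_small(self) -> bool:
        return self.norm <= 8

    @property
    def is_big(self) -> bool:
        return self.norm > 8

    def as_mapping(self) -> Mapping:
        return Mapping.from_cycles(
            [s.symbols for s in self.segments], len(self.reference.symbols)
        )

    @cached_property
    def is_connected(self) -> bool:
        segs = self.segments
        if len(segs) <= 1:
            return True
        ref = self.reference
        seen = {0}
        frontier = [0]
        while frontier:
            i = frontier.pop()
            for j in range(len(segs)):
                if j not in seen and (
                    intersects(segs[i], segs[j], ref)
                    or interleaves(segs[i], segs[j], ref)
                ):
                    seen.add(j)
                    frontier.append(j)
        return len(seen) == len(segs)

    # -- gates ---------------------------------------------------------------

    @cached_property
    def open_gates(self) -> tuple[tuple[int, int], ...]:
        """Consecutive pairs neither crossed by another pair nor completed to
        an oriented triplet inside their own segment."""
        ref = self.reference
        all_pairs = [p for s in self.segments for p in s.pairs()]
        gates = []
        for seg in self.segments:
            for a, b in seg.pairs():
                crossed = any(
                    _alternate((a, b), p, ref) for p in all_pairs if p != (a, b)
                )
                if crossed:
                    continue
                completed = any(
                    e not in (a, b) and is_oriented_triplet(a, b, e, ref)
                    for e in seg.symbols
                )
                if not completed:
                    gates.append((a, b))
        return tuple(gates)

    @property
    def is_full(self) -> bool:
        return not self.open_gates

    def __repr__(self) -> str:
        body = "".join(str(s) for s in self.segments)
        return f"Configuration({body}, norm={self.norm})"


def open_gates(config: Configuration) -> tuple[tuple[int, int], ...]:
    return config.open_gates


def is_full(config: Configuration) -> bool:
    return config.is_full


# ---------------------------------------------------------------------------
# Components
# ---------------------------------------------------------------------------


def components(sigma: Mapping, reference: ChromosomeCycle) -> tuple[Configuration, ...]:
    """Partition the residual's non-trivial cycles into components.

    Components are the connected classes under the intersect-or-interleave
    relation; a cycle connected to nothing forms a component by itself (the
    paper only needs that case for oriented cycles, but isolated cycles are
    reported uniformly).  Ordered by smallest support symbol.
    """
    cycles = sigma.nontrivial_cycles()
    segs = [segment_of(c) for c in cycles]
    k = len(segs)
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(k):
        for j in range(i + 1, k):
            if intersects(segs[i], segs[j], reference) or interleaves(
                segs[i], segs[j], reference
            ):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, list[Segment]] = {}
    for i in range(k):
        groups.setdefault(find(i), []).append(segs[i])
    comps = [Configuration(g, reference) for g in groups.values()]
    return tuple(sorted(comps, key=lambda c: min(c.support)))


def components_of(pi_bar: ChromosomeCycle) -> tuple[Configuration, ...]:
    return components(residual(pi_bar), pi_bar)


# ---------------------------------------------------------------------------
# Bad small components
# ---------------------------------------------------------------------------


class ComponentKind(enum.Enum):
    ORIENTED_SINGLETON = "oriented_singleton"
    BAD_ORIENTED_5CYCLE = "bad_oriented_5cycle"
    UNORIENTED_INTERLEAVING_PAIR = "unoriented_interleaving_pair"
    NECKLACE_4 = "necklace_4"
    NECKLACE_5 = "necklace_5"
    NECKLACE_6 = "necklace_6"
    TWISTED_NECKLACE_4 = "twisted_necklace_4"
    OTHER = "other"


BAD_KINDS = frozenset(
    {
        ComponentKind.BAD_ORIENTED_5CYCLE,
        ComponentKind.UNORIENTED_INTERLEAVING_PAIR,
        ComponentKind.NECKLACE_4,
        ComponentKind.NECKLACE_5,
        ComponentKind.NECKLACE_6,
        ComponentKind.TWISTED_NECKLACE_4,
    }
)


def is_bad_oriented_5cycle(seg: Segment, reference: ChromosomeCycle) -> bool:
    """The unique oriented-5-cycle shape that admits no 2-move.

    Written ``(a d b e c)`` with ``(a, b, c)`` oriented, its symbols sit in
    the chromosome as ``(a..b..c..d..e..)``.  Checked operationally: the
    cycle is oriented yet no applicable 3-cycle over its support is a
    2-move (both characterisations coincide; the operational one needs no
    relabelling).
    """
    if len(seg) != 5:
        raise ValidationError("bad-oriented-5-cycle test needs a 5-cycle")
    if not is_oriented(seg.symbols, reference):
        return False
    from .perm_core import _cycle_info, _move_delta_indexed, applicable_orientation

    sigma = residual(reference)
    info = _cycle_info(sigma)
    for trip in itertools.combinations(seg.symbols, 3):
        tau = applicable_orientation(trip, reference)
        if _move_delta_indexed(info, tau) == 2:
            return False
    return True


def classify_bad_small_component(config: Configuration) -> ComponentKind:
    """Match a component against the closed list of bad small components.

    Necklaces are recognised by intersection degree (each 3-cycle crosses
    exactly two others; the twisted size-4 variant has two cycles crossing
    all three others), not by pattern tables.
    """
    segs = config.segments
    ref = config.reference
    if len(segs) == 1:
        seg = segs[0]
        if len(seg) == 5 and is_bad_oriented_5cycle(seg, ref):
            return ComponentKind.BAD_ORIENTED_5CYCLE
        if is_oriented(seg.symbols, ref):
            return ComponentKind.ORIENTED_SINGLETON
        return ComponentKind.OTHER
    if any(len(s) != 3 for s in segs) or any(
        is_oriented(s.symbols, ref) for s in segs
    ):
        return ComponentKind.OTHER
    k = len(segs)
    if k == 2:
        if interleaves(segs[0], segs[1], ref) or interleaves(segs[1], segs[0], ref):
            return ComponentKind.UNORIENTED_INTERLEAVING_PAIR
        return ComponentKind.OTHER
    deg = [
        sum(
            1
            for j in range(k)
            if j != i and intersects(segs[i], segs[j], ref)
        )
        for i in range(k)
    ]
    if k in (4, 5, 6) and all(d == 2 for d in deg):
        return {
            4: ComponentKind.NECKLACE_4,
            5: ComponentKind.NECKLACE_5,
            6: ComponentKind.NECKLACE_6,
        }[k]
    if k == 4 and sorted(deg) == [2, 2, 3, 3]:
        return ComponentKind.TWISTED_NECKLACE_4
    return ComponentKind.OTHER


def is_bad_small_component(config: Configuration) -> bool:
    return (
        config.is_small and classify_bad_small_component(config) in BAD_KINDS
    )


# ---------------------------------------------------------------------------
# Sufficient extensions
# ---------------------------------------------------------------------------


def _candidate_3segments(
    config: Configuration, sigma: Mapping
) -> Iterator[Segment]:
    """Unoriented 3-cycle segments of residual cycles not yet in the
    configuration (every rotation start is a distinct candidate)."""
    used_parents = {s.parent for s in config.segments}
    ref = config.reference
    for cyc in sigma.nontrivial_cycles():
        if len(cyc) < 3:
            continue
        seg_full = segment_of(cyc)
        if seg_full.parent in used_parents:
            continue
        k = len(cyc)
        starts = range(k) if k > 3 else range(1)
        for i in starts:
            run = tuple(cyc[(i + j) % k] for j in range(3))
            if not is_oriented_triplet(*run, ref):
                yield Segment(run, seg_full.parent)


def _lengthened(seg: Segment) -> Iterator[Segment]:
    """Segments obtained by growing ``seg`` two symbols within its parent."""
    k = len(seg.parent)
    if len(seg) + 2 > k:
        return
    start = seg.parent.index(seg.symbols[0])
    for pre in (0, 1, 2):
        post = 2 - pre
        i = (start - pre) % k
        run = tuple(seg.parent[(i + j) % k] for j in range(len(seg) + 2))
        yield Segment(run, seg.parent)


def sufficient_extensions(config: Configuration) -> Iterator[Configuration]:
    """All one-step extensions raising the configuration's 3-norm by one.

    Three moves are allowed: (1) with open gates present, adjoin an
    unoriented 3-cycle segment that closes at least one of them; (2) on a
    full configuration, adjoin an unoriented 3-cycle segment crossing an
    existing one; (3) grow one segment by two symbols, either producing the
    bad oriented 5-cycle, or staying unoriented while closing a gate (gates
    present) / opening at most two new gates (full).
    """
    ref = config.reference
    sigma = residual(ref)
    gates = set(config.open_gates)
    others = list(config.segments)

    seen: set[tuple] = set()

    def emit(new_cfg: Configuration):
        key = tuple(s.symbols for s in new_cfg.segments)
        if key not in seen:
            seen.add(key)
            assert new_cfg.norm == config.norm + 1
            yield_list.append(new_cfg)

    yield_list: list[Configuration] = []

    if gates:
        for seg in _candidate_3segments(config, sigma):
            cfg2 = Configuration(others + [seg], ref)
            if any(g not in set(cfg2.open_gates) for g in gates):
                emit(cfg2)
    else:
        for seg in _candidate_3segments(config, sigma):
            if any(
                intersects(seg, s, ref)
                or interleaves(seg, s, ref)
                or interleaves(s, seg, ref)
                for s in others
            ):
                emit(Configuration(others + [seg], ref))

    for idx, seg in enumerate(others):
        rest = others[:idx] + others[idx + 1 :]
        for grown in _lengthened(seg):
            if set(grown.symbols) & (config.support - set(seg.symbols)):
                continue
            cfg2 = Configuration(rest + [grown], ref)
            ok = False
            if len(grown) == 5 and is_bad_oriented_5cycle(grown, ref):
                ok = True
            elif not is_oriented(grown.symbols, ref):
                if gates:
                    ok = any(g not in set(cfg2.open_gates) for g in gates)
                else:
                    ok = len(cfg2.open_gates) <= 2
            if ok:
                emit(cfg2)

    return iter(yield_list)
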