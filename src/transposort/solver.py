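"""The 1.375-approximation solver and its certificates.

Sorting proceeds in three phases.  First, a single (2,2)-sequence is applied
if one exists (found by complete look-ahead); this is what pushes the worst
case below 1.375 when the residual's 3-norm is small, because a permutation
with no (2,2)-sequence needs at least one 0-move, raising its true distance
one above the 3-norm lower bound.  Second, while the residual's 3-norm is at
least 8, guaranteed 11/8-sequences are applied.  Third, the remainder is
cleared greedily with 2-moves, falling back to (3,2)-sequences.

With ``m`` the 3-norm after the initial phase and
``f(m) = 11*floor(m/8) + floor(3*(m mod 8)/2)``, the move count ``t``
satisfies ``t <= f(m) + 2`` when a (2,2)-sequence was applied (distance
``>= m + 2``) and ``t <= f(m)`` otherwise (distance ``>= m + 1`` unless the
residual is a single oriented 3-cycle).  Both ratios are at most 11/8; every
solve carries the replayable sequence and these bounds as a checkable
certificate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

from .perm_core import (
    ChromosomeCycle,
    ThreeCycle,
    ValidationError,
    apply_3cycle,
    chromosome_from_one_line,
    f_upper,
    identity_chromosome,
    residual,
    three_norm,
)
from .move_search import (
    SearchBudget,
    SortingSequence,
    find_22_sequence,
    find_32_sequence,
    find_eleven_eighths_sequence,
    find_two_move,
)


@dataclass(frozen=True)
class SolveReport:
    """Full solve certificate for one chromosome."""

    permutation: tuple[int, ...]
    sequence: SortingSequence
    distance: int
    lower_bound: int
    upper_bound: int
    initial_norm: int
    used_22: bool

    @property
    def moves(self) -> tuple[int, ...]:
        return self.sequence.moves

    @property
    def ratio_vs_lower_bound(self) -> float:
        """Certified ratio against the case's distance lower bound.

        With a (2,2)-sequence the distance is at least the initial 3-norm
        ``m0``; without one (and ``m0 >= 2``) at least ``m0 + 1``, since at
        least one 0-move is then unavoidable.
        """
        if self.distance == 0:
            return 1.0
        m0 = self.initial_norm
        if self.used_22 or m0 <= 1:
            denom = max(m0, 1)
        else:
            denom = m0 + 1
        return self.distance / denom

    def to_json(self) -> str:
        return json.dumps(
            {
                "permutation": list(self.permutation),
                "distance": self.distance,
                "lower_bound": self.lower_bound,
                "upper_bound": self.upper_bound,
                "ratio_lb": round(self.ratio_vs_lower_bound, 6),
                "sequence": self.sequence.serialize(),
                "moves": list(self.moves),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SolveReport":
        d = json.loads(text)
        start = chromosome_from_one_line(d["permutation"])
        seq = SortingSequence.deserialize(d["sequence"], start)
        m0 = three_norm(residual(start))
        used_22 = len(seq.moves) >= 2 and seq.moves[0] == 2 and seq.moves[1] == 2
        return cls(
            tuple(d["permutation"]),
            seq,
            d["distance"],
            d["lower_bound"],
            d["upper_bound"],
            m0,
            used_22,
        )


def sort_by_transpositions(
    p: Sequence[int], budget: SearchBudget = SearchBudget()
) -> SolveReport:
    """Sort a one-line permutation, returning the certificate report.

    Ties among candidate moves are broken by the deterministic candidate
    order (canonical cycles, lexicographic triples), so identical inputs
    always produce identical reports.
    """
    start = chromosome_from_one_line(p)
    m0 = three_norm(residual(start))
    taus: list[ThreeCycle] = []
    cur = start
    used_22 = False

    seq22 = find_22_sequence(cur)
    if seq22 is not None:
        used_22 = True
        for tau in seq22.taus:
            taus.append(tau)
            cur = apply_3cycle(tau, cur)

    while three_norm(residual(cur)) >= 8:
        seq = find_eleven_eighths_sequence(cur, budget)
        for tau in seq.taus:
            taus.append(tau)
            cur = apply_3cycle(tau, cur)

    while not residual(cur).is_identity():
        tau = find_two_move(cur)
        if tau is not None:
            taus.append(tau)
            cur = apply_3cycle(tau, cur)
            continue
        seq = find_32_sequence(cur)
        for tau in seq.taus:
            taus.append(tau)
            cur = apply_3cycle(tau, cur)

    sequence = SortingSequence.build(taus, start)
    report = SolveReport(
        permutation=tuple(p),
        sequence=sequence,
        distance=len(taus),
        lower_bound=m0,
        upper_bound=f_upper(m0 - 2) + 2 if used_22 else f_upper(m0),
        initial_norm=m0,
        used_22=used_22,
    )
    if not certify(report):
        raise SearchFailure(
            f"internal certificate violation for permutation {tuple(p)}: "
            f"{report.to_json()}"
        )
    return report


class SearchFailure(RuntimeError):
    """A solve produced a sequence violating its own certificate."""


def certify(report: SolveReport) -> bool:
    """Re-validate a report from scratch.

    Checks: the sequence replays cleanly and sorts the chromosome; the
    distance lies between the 3-norm lower bound and both the per-case
    accounting bound and the unconditional ``f(m0)`` bound.
    """
    try:
        start = chromosome_from_one_line(report.permutation)
    except ValidationError:
        return False
    seq = report.sequence
    if seq.start != start or not seq.validate():
        return False
    if seq.end != identity_chromosome(start.n):
        return False
    if report.distance != seq.x:
        return False
    m0 = three_norm(residual(start))
    if report.lower_bound != m0 or report.distance < m0:
        return False
    case_bound = f_upper(m0 - 2) + 2 if report.used_22 else f_upper(m0)
    if report.distance > case_bound or report.distance > f_upper(m0):
        return False
    if report.upper_bound != case_bound:
        return False
    return True
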