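"""Guaranteed move sequences: 2-moves, look-ahead, (3,2), (4,3), 11/8."""

import itertools

import pytest

from transposort import (
    ComponentKind,
    SearchBudget,
    SortingSequence,
    ThreeCycle,
    ValidationError,
    apply_3cycle,
    bounded_search,
    chromosome_from_one_line,
    chromosome_with_components,
    classify_move,
    find_22_sequence,
    find_32_sequence,
    find_43_sequence,
    find_eleven_eighths_sequence,
    find_two_move,
    fixture_from_component_spec,
    identity_chromosome,
    residual,
    three_norm,
)
from transposort.move_search import iter_two_moves
from transposort.perm_core import applicable_orientation

IP = ComponentKind.UNORIENTED_INTERLEAVING_PAIR
BAD5 = ComponentKind.BAD_ORIENTED_5CYCLE
N4 = ComponentKind.NECKLACE_4


def brute_force_two_move_exists(pb):
    """Independent oracle: test every applicable 3-cycle on the chromosome."""
    for trip in itertools.combinations(range(pb.n + 1), 3):
        tau = applicable_orientation(trip, pb)
        if classify_move(tau, pb) == 2:
            return True
    return False


class TestTwoMoves:
    def test_two_move_on_even_cycle_example(self, ex_intersect):
        tau = find_two_move(ex_intersect)
        assert tau is not None
        assert classify_move(tau, ex_intersect) == 2

    def test_identity_has_no_two_move(self):
        assert find_two_move(identity_chromosome(6)) is None

    def test_oriented_3cycle_is_its_own_two_move(self):
        # find a chromosome whose residual is one oriented 3-cycle
        for p in itertools.permutations(range(1, 4)):
            pb = chromosome_from_one_line(p)
            cycles = residual(pb).nontrivial_cycles()
            if len(cycles) == 1 and len(cycles[0]) == 3:
                tau = find_two_move(pb)
                assert tau is not None
                assert set(tau.symbols) == set(cycles[0])

    def test_deterministic(self, ex_intersect):
        assert find_two_move(ex_intersect) == find_two_move(ex_intersect)

    def test_completeness_exhaustive_small(self):
        """find_two_move returns None only when no 2-move exists at all
        (every applicable 3-cycle checked), exhaustively for n <= 6."""
        for n in range(2, 7):
            for p in itertools.permutations(range(1, n + 1)):
                pb = chromosome_from_one_line(p)
                got = find_two_move(pb) is not None
                assert got == brute_force_two_move_exists(pb)


class TestLookAhead:
    def test_22_found_on_intermediate_of_printed_sequence(self, ex_sequence):
        mid = apply_3cycle(ThreeCycle(1, 4, 7), ex_sequence)
        seq = find_22_sequence(mid)
        assert seq is not None
        assert (seq.x, seq.y) == (2, 2)
        assert seq.validate()

    def test_no_22_on_bad_five_cycle(self):
        pb = fixture_from_component_spec(BAD5)
        assert find_two_move(pb) is None
        assert find_22_sequence(pb) is None

    def test_no_22_on_identity(self):
        assert find_22_sequence(identity_chromosome(5)) is None


class TestThreeTwo:
    def test_interleaving_pair_gives_32(self):
        pb = fixture_from_component_spec(IP)
        seq = find_32_sequence(pb)
        assert seq.x == 3 and seq.y >= 2
        assert seq.validate()
        assert seq.moves[0] == 0

    def test_bad_five_cycle_gives_32(self):
        pb = fixture_from_component_spec(BAD5)
        seq = find_32_sequence(pb)
        assert seq.x == 3 and seq.y >= 2
        assert seq.validate()

    def test_raises_on_sorted_chromosome(self):
        with pytest.raises(ValidationError):
            find_32_sequence(identity_chromosome(4))


class TestFourThree:
    def test_no_two_move_oriented_7cycle(self):
        # the unique 6-symbol chromosome whose residual is an oriented
        # 7-cycle without any 2-move
        pb = chromosome_from_one_line([3, 6, 2, 5, 1, 4])
        (gamma,) = residual(pb).nontrivial_cycles()
        assert find_two_move(pb) is None
        seq = find_43_sequence(pb, gamma)
        assert (seq.x, seq.y) == (4, 3)
        assert seq.validate()
        assert sum(1 for m in seq.moves if m == 2) == 3

    def test_guards(self, ex_sequence):
        with pytest.raises(ValidationError):
            find_43_sequence(ex_sequence, (1, 7, 4))  # too short
        pb = chromosome_from_one_line([3, 6, 2, 5, 1, 4])
        with pytest.raises(ValidationError):
            find_43_sequence(pb, (0, 1, 2, 3, 4, 5, 6))  # not a residual cycle


class TestBoundedSearch:
    def test_single_oriented_3cycle_found_at_length_one(self):
        for p in itertools.permutations(range(1, 4)):
            pb = chromosome_from_one_line(p)
            cycles = residual(pb).nontrivial_cycles()
            if len(cycles) == 1 and len(cycles[0]) == 3:
                seq = bounded_search(pb, set(cycles[0]), SearchBudget(max_len=3))
                assert seq is not None and seq.x == 1

    def test_interleaving_pair_32_pattern(self):
        pb = fixture_from_component_spec(IP)
        seq = bounded_search(
            pb,
            residual(pb).support,
            SearchBudget(max_len=3),
            accept=lambda x, y: x <= 3 and y >= 2,
            deficit_schedule={0: 1, 1: 3},
        )
        assert seq is not None
        assert (seq.x, seq.y) == (3, 2)

    def test_ratio_arithmetic_of_sequences(self, ex_sequence):
        taus = [ThreeCycle(1, 4, 7), ThreeCycle(2, 8, 5), ThreeCycle(1, 4, 7)]
        seq32 = SortingSequence.build(taus, ex_sequence)
        assert not seq32.is_eleven_eighths  # 3/2 > 11/8
        taus43 = taus + [ThreeCycle(3, 9, 6)]
        seq43 = SortingSequence.build(taus43, ex_sequence)
        assert seq43.is_eleven_eighths

    def test_no_sequence_inside_bad_components(self):
        """The bad small components admit no internal 11/8-sequence (for the
        two smallest supports the search space is exhausted; for the larger
        necklaces the assertion is within the test budget)."""
        budgets = {
            BAD5: 20_000,
            IP: 20_000,
            N4: 20_000,
            ComponentKind.TWISTED_NECKLACE_4: 20_000,
        }
        for kind, nodes in budgets.items():
            pb = fixture_from_component_spec(kind)
            seq = bounded_search(
                pb, residual(pb).support, SearchBudget(max_nodes=nodes)
            )
            assert seq is None, f"{kind} admitted internal {seq}"


class TestElevenEighths:
    def test_printed_sequence_is_eleven_eighths(self, ex_sequence):
        seq = SortingSequence.build(
            [
                ThreeCycle(1, 4, 7),
                ThreeCycle(2, 8, 5),
                ThreeCycle(1, 4, 7),
                ThreeCycle(3, 9, 6),
            ],
            ex_sequence,
        )
        assert (seq.x, seq.y) == (4, 3)
        assert seq.is_eleven_eighths

    def test_two_move_is_a_qualifying_sequence(self):
        # a norm-8 residual with an even cycle: 2-move available
        pb = chromosome_from_one_line(
            [2, 1, 4, 3, 6, 5, 8, 7, 10, 9, 12, 11, 14, 13, 16, 15]
        )
        assert three_norm(residual(pb)) >= 8
        seq = find_eleven_eighths_sequence(pb)
        assert seq.x == 1 and seq.y == 1

    def test_norm_below_eight_rejected(self, ex_sequence):
        with pytest.raises(ValidationError):
            find_eleven_eighths_sequence(ex_sequence)

    @pytest.mark.parametrize(
        "kinds",
        [
            [BAD5, BAD5, BAD5, BAD5],
            [BAD5, BAD5, IP, IP],
            [IP, IP, N4],
            [ComponentKind.TWISTED_NECKLACE_4, IP, IP],
            [ComponentKind.NECKLACE_5, IP, BAD5],
        ],
        ids=["4xbad5", "2bad5+2ip", "2ip+necklace4", "twisted+2ip", "necklace5+ip+bad5"],
    )
    def test_bad_component_unions_yield_sequences(self, kinds):
        """Unions of bad small components of total norm >= 8 allow an
        11/8-sequence, found by the staged bounded search."""
        pb = chromosome_with_components(kinds)
        assert find_two_move(pb) is None
        assert three_norm(residual(pb)) >= 8
        seq = find_eleven_eighths_sequence(pb)
        assert seq.validate()
        assert seq.is_eleven_eighths
        # norm drops by exactly the number of 2-moves (no (-2)-moves taken)
        after = seq.end
        assert three_norm(residual(after)) == three_norm(residual(pb)) - seq.y


class TestSequenceReplay:
    def test_validate_detects_corruption(self, ex_sequence):
        seq = SortingSequence.build(
            [ThreeCycle(1, 4, 7), ThreeCycle(2, 8, 5)], ex_sequence
        )
        assert seq.validate()
        broken = SortingSequence(seq.taus[1:], seq.start, seq.moves[1:])
        assert not broken.validate()

    def test_serialization_round_trip(self, ex_sequence):
        seq = SortingSequence.build(
            [ThreeCycle(1, 4, 7), ThreeCycle(2, 8, 5)], ex_sequence
        )
        text = seq.serialize()
        assert text == "1,4,7;2,8,5"
        back = SortingSequence.deserialize(text, ex_sequence)
        assert back == seq
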