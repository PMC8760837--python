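"""Permutation-group arithmetic: construction, products, residuals, bounds."""

import itertools
import random
from collections import deque

import pytest

from transposort import (
    ChromosomeCycle,
    Mapping,
    ThreeCycle,
    ValidationError,
    apply_3cycle,
    chromosome_from_one_line,
    chromosome_from_residual,
    classify_move,
    diameter_upper_bound,
    f_upper,
    identity_chromosome,
    is_applicable,
    lower_bound,
    residual,
    three_norm,
)
from transposort.perm_core import (
    applicable_orientation,
    cycle_string,
    inverse,
    iter_permutation_lines,
    parse_one_line,
)


def random_chromosome(rng, n):
    p = list(range(1, n + 1))
    rng.shuffle(p)
    return chromosome_from_one_line(p)


class TestConstruction:
    def test_from_one_line_examples(self):
        pb = chromosome_from_one_line([8, 7, 6, 5, 1, 4, 9, 3, 2])
        assert pb.symbols == (0, 8, 7, 6, 5, 1, 4, 9, 3, 2)
        assert pb.one_line() == (8, 7, 6, 5, 1, 4, 9, 3, 2)
        assert chromosome_from_one_line([1, 2, 3]) == identity_chromosome(3)
        assert chromosome_from_one_line([2, 1]).symbols == (0, 2, 1)

    @pytest.mark.parametrize(
        "bad", [[1, 1, 2], [0, 1, 2], [1, 2, 4], [], [3, 3]]
    )
    def test_invalid_one_line_rejected(self, bad):
        with pytest.raises(ValidationError):
            chromosome_from_one_line(bad)

    def test_inverse_reverses_cyclic_order(self, ex_intersect):
        assert ex_intersect.inverse().symbols == (0, 2, 3, 9, 4, 1, 5, 6, 7, 8)
        assert inverse(identity_chromosome(3)).symbols == (0, 3, 2, 1)

    def test_inverse_is_involution(self):
        rng = random.Random(0)
        for _ in range(100):
            pb = random_chromosome(rng, rng.randint(1, 20))
            assert pb.inverse().inverse() == pb
            m = pb.as_mapping()
            assert m.inverse().inverse() == m


class TestProducts:
    def test_applicable_product_is_single_cycle(self):
        tau = Mapping.from_cycles([(0, 2, 7)], 9)
        pb = Mapping.from_cycles([(0, 4, 3, 2, 1, 8, 7, 6, 5)], 9)
        assert cycle_string(tau * pb) == "(0 4 3 7 6 5 2 1 8)"

    def test_non_applicable_product_splits(self):
        tau = Mapping.from_cycles([(0, 1, 2)], 9)
        pb = Mapping.from_cycles([(0, 4, 3, 2, 1, 8, 7, 6, 5)], 9)
        assert cycle_string(tau * pb) == "(0 4 3)(1 8 7 6 5)"

    def test_product_with_inverse_is_identity(self):
        rng = random.Random(1)
        for _ in range(50):
            n = rng.randint(2, 15)
            img = list(range(n))
            rng.shuffle(img)
            alpha = Mapping(img)
            assert (alpha * alpha.inverse()).is_identity()

    def test_ground_set_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            Mapping.identity(3) * Mapping.identity(4)


class TestCyclesAndNorm:
    def test_disjoint_cycle_decomposition(self):
        # one-line [4 8 3 7 2 6 1 5] on 1..8, with 0 fixed
        rho = Mapping([0, 4, 8, 3, 7, 2, 6, 1, 5])
        assert rho.nontrivial_cycles() == ((1, 4, 7), (2, 8, 5))
        assert rho.c_odd == 5  # two 3-cycles plus fixed 0, 3, 6
        assert three_norm(rho) == 2

    def test_identity_cycles(self):
        ident = Mapping.identity(10)
        assert ident.c_odd == 10
        assert three_norm(ident) == 0

    def test_three_norm_undefined_for_odd(self):
        with pytest.raises(ValidationError):
            three_norm(Mapping.from_cycles([(0, 1)], 4))

    def test_three_norm_matches_bruteforce_factorisation(self):
        """3-norm equals the BFS distance in the Cayley graph generated by
        all 3-cycles, checked exhaustively on up to 6 symbols."""
        for n in (4, 5, 6):
            gens = [
                Mapping.from_cycles([trip], n)
                for trip in itertools.permutations(range(n), 3)
            ]
            start = Mapping.identity(n)
            dist = {start: 0}
            queue = deque([start])
            while queue:
                alpha = queue.popleft()
                for g in gens:
                    beta = g * alpha
                    if beta not in dist:
                        dist[beta] = dist[alpha] + 1
                        queue.append(beta)
            for alpha, d in dist.items():
                assert three_norm(alpha) == d


class TestResidual:
    def test_residual_examples(self, ex_intersect, ex_sequence):
        assert cycle_string(residual(ex_intersect)) == "(0 3)(1 6 8)(2 4)(5 7 9)"
        assert (
            cycle_string(residual(ex_sequence))
            == "(0 11 13)(1 7 4)(2 8 5)(3 9 6)(10 12 14)"
        )
        assert residual(identity_chromosome(6)).is_identity()

    def test_residual_is_always_even(self):
        rng = random.Random(2)
        for _ in range(300):
            pb = random_chromosome(rng, rng.randint(1, 16))
            assert residual(pb).is_even

    def test_round_trip_with_chromosome(self, ex_intersect):
        sigma = Mapping.from_cycles([(0, 3), (1, 6, 8), (2, 4), (5, 7, 9)], 10)
        assert chromosome_from_residual(sigma, 9) == ex_intersect
        assert chromosome_from_residual(Mapping.identity(6), 5) == identity_chromosome(5)
        rng = random.Random(3)
        for _ in range(100):
            pb = random_chromosome(rng, rng.randint(1, 12))
            assert chromosome_from_residual(residual(pb), pb.n) == pb

    def test_non_realizable_residual_rejected(self):
        sigma = Mapping.from_cycles([(0, 1, 2), (3, 4, 5)], 6)
        with pytest.raises(ValidationError):
            chromosome_from_residual(sigma, 5)


class TestMoves:
    def test_applicability(self, ex_product):
        assert is_applicable(ThreeCycle(0, 2, 7), ex_product)
        assert not is_applicable(ThreeCycle(0, 1, 2), ex_product)
        ident = identity_chromosome(9)
        for a, b, c in itertools.combinations(range(10), 3):
            assert is_applicable(ThreeCycle(a, b, c), ident)

    def test_three_cycle_canonical_rotation(self):
        assert ThreeCycle(2, 7, 0) == ThreeCycle(0, 2, 7)
        assert ThreeCycle(7, 0, 2) == ThreeCycle(0, 2, 7)
        assert ThreeCycle(0, 7, 2) != ThreeCycle(0, 2, 7)
        with pytest.raises(ValidationError):
            ThreeCycle(1, 1, 2)

    def test_apply_examples(self, ex_product, ex_sequence):
        applied = apply_3cycle(ThreeCycle(0, 2, 7), ex_product)
        assert applied.symbols == (0, 4, 3, 7, 6, 5, 2, 1, 8)
        after = apply_3cycle(ThreeCycle(1, 4, 7), ex_sequence)
        assert after.symbols == (0, 7, 2, 6, 4, 8, 3, 1, 5, 9, 14, 13, 12, 11, 10)

    def test_apply_rejects_non_applicable(self, ex_product):
        with pytest.raises(ValidationError):
            apply_3cycle(ThreeCycle(0, 1, 2), ex_product)

    def test_residual_update_law(self):
        """Applying tau multiplies the residual by tau**-1 on the right."""
        rng = random.Random(4)
        for _ in range(200):
            pb = random_chromosome(rng, rng.randint(3, 12))
            trip = rng.sample(range(pb.n + 1), 3)
            tau = applicable_orientation(trip, pb)
            lhs = residual(apply_3cycle(tau, pb))
            rhs = residual(pb) * tau.inverse().as_mapping(pb.n + 1)
            assert lhs == rhs

    def test_classify_move_on_printed_sequence(self, ex_sequence):
        tau1 = ThreeCycle(1, 4, 7)
        assert classify_move(tau1, ex_sequence) == 0
        mid = apply_3cycle(tau1, ex_sequence)
        assert classify_move(ThreeCycle(2, 8, 5), mid) == 2

    def test_move_class_membership(self):
        rng = random.Random(5)
        for _ in range(500):
            pb = random_chromosome(rng, rng.randint(3, 14))
            trip = rng.sample(range(pb.n + 1), 3)
            tau = applicable_orientation(trip, pb)
            mu = classify_move(tau, pb)
            assert mu in (-2, 0, 2)
            # cross-check against a direct odd-cycle-count recomputation
            assert mu == residual(apply_3cycle(tau, pb)).c_odd - residual(pb).c_odd


class TestBounds:
    def test_lower_bound_examples(self, ex_intersect, ex_components):
        assert lower_bound(identity_chromosome(5)) == 0
        assert lower_bound(ex_intersect) == 4
        assert lower_bound(ex_components) == 5

    def test_f_upper(self):
        assert f_upper(0) == 0
        assert f_upper(8) == 11
        assert f_upper(5) == 7
        with pytest.raises(ValidationError):
            f_upper(-1)

    def test_diameter_bound_beats_three_quarters(self):
        assert diameter_upper_bound(16) == 11
        assert diameter_upper_bound(16) < (3 * 16) // 4
        with pytest.raises(ValidationError):
            diameter_upper_bound(0)


class TestTextFormat:
    def test_parse_one_line(self):
        assert parse_one_line("2 1 3") == (2, 1, 3)
        for bad in ("1 1 2", "0 1", "1 2 x", ""):
            with pytest.raises(ValidationError):
                parse_one_line(bad)

    def test_iter_lines_skips_comments_and_reports_line_numbers(self):
        lines = ["# comment", "1 2 3", "", "2 1 3"]
        parsed = list(iter_permutation_lines(lines))
        assert parsed == [(2, (1, 2, 3)), (4, (2, 1, 3))]
        with pytest.raises(ValidationError, match="line 2"):
            list(iter_permutation_lines(["1 2", "1 1 2"]))
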