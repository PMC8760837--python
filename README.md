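# transposort

Sorting by transpositions with a certified 1.375 approximation ratio.

A *transposition* is the genome-rearrangement event that swaps two adjacent
blocks of genes in a chromosome. With genes encoded as the integers
`1..n`, computing the minimum number of transpositions that sorts a
permutation (the transposition distance, SBT) is NP-hard, so practical
tools rely on approximation algorithms with guaranteed ratios.

`transposort` implements an algebraic 1.375-approximation that operates on
permutation-group structure instead of the classical cycle graph — and in
particular never *simplifies* (inserts symbols into) the input, which is
the known source of ratio violations in the classical 1.375 approach:

- the chromosome `π = [π₁ … πₙ]` is the (n+1)-cycle `π̄ = (0 π₁ … πₙ)`;
- a transposition is the left product `τπ̄` by an *applicable* 3-cycle
  `τ = (a b c)` (its symbols occur in `π̄` in that cyclic order);
- all structure lives in the residual permutation `ῑπ̄⁻¹` (where
  `ῑ = (0 1 … n)`), whose disjoint cycles, orientation and
  intersection/interleaving pattern determine which guaranteed move
  sequences exist.

With `c°odd` the number of odd-length cycles of the residual and
`‖·‖₃ = (n+1−c°odd)/2` its 3-norm (the sorting lower bound), the solver
applies, in order: one (2,2)-sequence found by complete look-ahead (two
consecutive 2-moves, each raising `c°odd` by 2); 11/8-sequences while
`‖ῑπ̄⁻¹‖₃ ≥ 8`; then 2-moves and (3,2)-sequences. Writing
`f(m) = 11⌊m/8⌋ + ⌊3(m mod 8)/2⌋`, the computed distance `t` satisfies
`t ≤ f(m)+2` with a (2,2)-sequence (true distance ≥ m+2) and `t ≤ f(m)`
without one (true distance ≥ m+1), so `t/d(π̄) ≤ 11/8 = 1.375` in every
case. Each solve returns the transposition sequence itself plus a
replayable certificate of these bounds.

An exhaustive BFS oracle provides exact distances for small genomes
(`n ≤ 11`), used to validate the solver and to reproduce reference
statistics.

## Worked example

```
$ transposort sort "8 7 6 5 1 4 9 3 2"
{"distance": 5, "lower_bound": 4, "moves": [2, 2, 0, 2, 2], "permutation":
[8, 7, 6, 5, 1, 4, 9, 3, 2], "ratio_lb": 1.25, "sequence":
"0,3,2;0,4,2;1,8,6;5,7,9;1,8,6", "upper_bound": 5}
```

The residual of this chromosome is `(0 3)(1 6 8)(2 4)(5 7 9)`: ten symbols
of which two form odd cycles, so the 3-norm lower bound is `(10−2)/2 = 4`.
The solver opens with a (2,2)-sequence (the first two `moves` are 2-moves)
and sorts in five transpositions: one 0-move was unavoidable here, and the
certified ratio against the lower bound is `5/4 = 1.25 ≤ 1.375`
(`ratio_lb`). The `sequence` field lists the applied 3-cycles
`(0 3 2)(0 4 2)(1 8 6)(5 7 9)(1 8 6)`; replaying them on the chromosome is
exactly the certificate check `transposort` performs before returning, and
`upper_bound` is the case bound `f(m₀−2)+2 = 5` it is checked against.

Other entry points: `transposort distance --exact` (BFS oracle),
`transposort sweep N` (exhaustive statistics over S_N), `transposort
bounds` (3-norm lower bound and `f` upper bound), `transposort random`
(seeded benchmark inputs), `transposort fixture KIND` (chromosomes whose
residuals realize the named bad small component).

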