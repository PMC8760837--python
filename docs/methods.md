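# Methods

## Model

A chromosome with `n` genes and no duplicates is the permutation
`π = [π₁ … πₙ]`; the package represents it as the (n+1)-cycle
`π̄ = (0 π₁ … πₙ)` over `{0,…,n}` and the sorted state as
`ῑ = (0 1 … n)`. A transposition (exchange of two adjacent gene blocks) is
the left product of `π̄` by an applicable 3-cycle `(a b c)` — one whose
symbols occur in `π̄` in that cyclic order; any other 3-cycle splits the
product into several cycles and so does not describe a chromosome. Sorting
in `t` transpositions is equivalent to factoring the *residual*
`ῑπ̄⁻¹` into `t` applicable 3-cycles. The composition convention is
`(αβ)(x) = α(β(x))` throughout.

The residual is always an even permutation. With `c°odd` its number of
odd-length cycles (fixed points included), its 3-norm
`‖ῑπ̄⁻¹‖₃ = (n+1−c°odd)/2` is a lower bound on the distance, because each
transposition contributes a single 3-cycle factor. Applying an applicable
3-cycle changes `c°odd` by −2, 0 or +2 (`μ`-moves); a 2-move (μ = +2)
lowers the 3-norm by exactly one. All further structure — orientation of
residual cycles, intersection and interleaving, components, open gates —
is read off the cyclic order of symbols around `π̄`, never from a separate
graph structure.

## The solver

`sort_by_transpositions` runs three phases:

1. **(2,2) look-ahead.** Every 2-move is enumerated (complete: a 2-move's
   symbols lie within one residual cycle, or two symbols in one even cycle
   and one in another even cycle — a parity count over the possible cycle
   redistributions rules out everything else). For each first 2-move the
   solver checks whether any second 2-move exists; the first such pair is
   applied. At most one (2,2)-sequence is applied, at the start: its role
   is purely the accounting below, and later 2-moves arise naturally.
2. **11/8-sequences** while `‖ῑπ̄⁻¹‖₃ ≥ 8` (an (x,y)-sequence — x moves of
   which y are 2-moves — with `x ≤ 11` and `x/y ≤ 11/8`). In order: a bare
   2-move (a (1,1)-sequence); a (4,3)-sequence inside a long oriented odd
   cycle; a bounded search over the support of a small component that is
   not on the bad list; a bounded search over a sufficient configuration
   grown to 3-norm 9 inside a big component; a bounded search over a
   growing union of bad small components (largest norm first, re-searched
   after each addition — the same incremental procedure the underlying
   case analysis uses, which never needed unions of norm above 8).
3. **Cleanup:** greedy 2-moves, else (3,2)-sequences, until the residual
   is the identity. A (3,2)-sequence always exists when no 2-move does.

**Certificate.** With `m₀` the initial 3-norm and
`f(m) = 11⌊m/8⌋ + ⌊3(m mod 8)/2⌋`, the solve is checked against
`t ≤ f(m₀−2)+2` when a (2,2)-sequence was applied (true distance ≥ m₀) and
`t ≤ f(m₀)` otherwise (true distance ≥ m₀+1 when m₀ ≥ 2, since a 0-move is
then unavoidable). Both give `t/d ≤ 11/8`. `certify` replays the sequence
from scratch and re-derives every bound; a violation is a hard error,
never a silently degraded answer.

## Guaranteed-sequence search

Proof-pattern moves are never transcribed from the case analysis; every
sequence is found by `bounded_search` over a bounded symbol support and
re-validated move by move. Design of the search:

- **Move family.** Candidates are applicable 3-cycles whose symbols lie in
  one residual cycle or span exactly two (a three-cycle-spanning move can
  never be a 2-move, and is a (−2)-move whenever all three cycles are odd
  — the only regime in which the deep searches run). (−2)-moves are never
  taken, so every returned sequence strictly lowers the 3-norm, which is
  what makes the solver's progress argument unconditional.
- **Deficit staging.** The search deepens over the number of 0-moves: a
  one-0-move cascade (a (4,3)) is searched exhaustively before the
  (8,6)-shaped level opens, and (11,8) last. A prefix with `d` 0-moves is
  pruned unless `⌈11d/3⌉` moves fit in the length budget, and a
  ratio-amortisation prune discards states whose gap `8x−11y` cannot close
  within the remaining length or the 3-norm still present in the support.
- **Ordering.** 2-moves first, lexicographic within a class; at nodes
  without any 2-move, candidate 0-moves are ranked by a one-step lookahead
  (how many 2-moves each enables) and only the best `zero_beam` (default
  12) are expanded. Memoisation keeps the first (length, deficit)-minimal
  visit of each state. No randomness anywhere: identical inputs give
  identical sequences.
- **Budgets.** `SearchBudget` defaults to depth 11 and 300 000 state
  expansions; the staged schedule uses 50k/200k/200k nodes for the three
  deficit levels. Budget exhaustion in a context where theory guarantees a
  sequence raises `SearchExhausted` with the offending state — an explicit
  bug-report artifact — rather than weakening the certificate.

## Oracle and statistics

Exact distances come from breadth-first search over one-line permutation
states with all `C(n+1,3)` block transpositions as generators (the set is
closed under inversion, so BFS layers from the identity are distances).
The table for a given `n` is cached per process; `n ≤ 11` is the
documented cap (the table stores all `n!` states). Averages over S_n
follow the convention sum/(n!−1) — over non-identity permutations — and
all reported decimals are truncated, not rounded (4 places for distances
and ratios, 2 for percentages). These conventions reproduce the published
small-`n` reference averages digit for digit. For genomes beyond the
oracle range, the harness reports distance against the 3-norm lower bound
and labels it a *bound ratio*: an upper bound on the true approximation
ratio, not the ratio itself.

## Fixtures as synthetic data

Benchmark inputs are uniform random permutations from a seeded
Fisher–Yates shuffle — the standard null model in this literature. They
emulate gene orders with no duplicated genes, a single chromosome and no
intergenic information; they do not emulate phylogenetic correlation
between genomes, so passing tests say nothing about distances between
closely related real genomes, only about the solver's guarantees per
input.

Structure fixtures are chromosomes whose residuals realize prescribed
components. Each bad small component — the bad oriented 5-cycle, the
unoriented interleaving pair, the unoriented necklaces of sizes 4–6 and
the twisted necklace of size 4 — is stored as a residual-cycle pattern
found by backtracking search over chromosome circular orders and
re-validated by the classifiers at build time. The printed
intersection-degree definition of a necklace admits configurations that do
allow internal cascades; the stored representatives were additionally
filtered so that the bounded search finds no internal 11/8-sequence, which
is the operative meaning of *bad*. Multi-component fixtures stack patterns
on consecutive symbol blocks; the block boundaries are crossed exactly
once each by the chromosome walk, keeping the product a single cycle, and
the assembled residual's component multiset is re-verified.

## Numerical and design choices

- Symbols are 0-based; `π̄` is stored linearly in canonical rotation
  starting at 0 with a position index, making cyclic-order queries O(1).
  The index is rebuilt (O(n)) on each applied transposition — simplicity
  over asymptotics, as the supported scales are small.
- `ThreeCycle` canonicalizes to the rotation with the smallest symbol
  first; deterministic iteration is lexicographic on that form. Tie-breaks
  among equally good moves follow the candidate enumeration order
  (canonical cycle order, ascending triples). Tie-break-dependent
  statistics (percent-equal, average computed distance) are therefore
  implementation-specific and are reported, not asserted.
- Configurations treat each stored segment as a cycle of its own (wrap
  pair included); the 3-norm of a configuration is computed from segment
  lengths by the same odd-cycle formula.
- Sufficient extensions are applied *online* to segments of the actual
  residual (adjoin an unoriented 3-cycle segment that closes an open gate;
  adjoin a crossing segment when full; grow a segment by two symbols under
  the stated gate rules), rather than to abstract relabelled
  configurations as in the offline analysis.
- Test and validation scales: exhaustive sweeps use `n ≤ 8` (40 320
  permutations) for the safety-net and completeness properties, all 5040
  permutations of `n = 7` for the ratio certificate, and `n ≤ 6` for
  oracle cross-checks; union fixtures stay within 27 symbols. These sizes
  keep every guarantee exercised end to end while the whole suite runs in
  minutes.

## Known limitations

- The bounded search's restricted move family and budgets are sufficient
  for every fixture and sweep in the test suite, but a residual consisting
  solely of four or more *pairwise distant* norm-2 bad components (e.g.
  four interleaving pairs on well-separated arcs, first possible at
  n ≥ 23) can exhaust the staged budgets without producing the
  theoretically guaranteed (11,8)-sequence; the solver then raises
  `SearchExhausted` instead of returning an uncertified answer.
- The exact oracle keeps all `n!` states in memory; beyond `n = 11` use
  the solver plus the analytic bounds.
- The worst-case time complexity of the solver is not optimised; the
  implementation favours verifiable certificates over the asymptotically
  faster engineering known for this problem.
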