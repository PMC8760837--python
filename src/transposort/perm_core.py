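"""Exact permutation-group arithmetic for sorting by transpositions.

A chromosome with genes ``1..n`` in one-line notation ``[p1 .. pn]`` is
modelled as the ``(n+1)``-cycle ``pi_bar = (0 p1 .. pn)`` on the ground set
``{0,..,n}``; the sorted chromosome is the cycle ``iota_bar = (0 1 .. n)``.
A genomic transposition (swap of two adjacent gene blocks) is the left
multiplication of ``pi_bar`` by an *applicable* 3-cycle ``(a b c)``: one whose
symbols occur in ``pi_bar`` in that same cyclic order.  Sorting ``pi_bar``
with ``t`` transpositions is then the factorisation of the residual
permutation ``iota_bar * pi_bar**-1`` into ``t`` applicable 3-cycles, which is
what the whole package analyses.

Composition convention: ``(alpha * beta)(x) = alpha(beta(x))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Iterator, Sequence


class ValidationError(ValueError):
    """Raised for inputs that do not satisfy a documented precondition."""


# ---------------------------------------------------------------------------
# Mapping: a dense bijection on {0..N-1}
# ---------------------------------------------------------------------------


class Mapping:
    """A permutation of the ground set ``{0,..,N-1}`` stored as an image array.

    Ground sets in this package are small (a few hundred symbols at most), so
    a dense tuple is both the simplest and the fastest representation.
    """

    __slots__ = ("image", "_cycles", "_hash")

    def __init__(self, image: Sequence[int]):
        img = tuple(image)
        n = len(img)
        seen = bytearray(n)
        for y in img:
            if not 0 <= y < n or seen[y]:
                raise ValidationError(f"not a bijection on 0..{n - 1}: image {img}")
            seen[y] = 1
        self.image = img
        self._cycles: tuple[tuple[int, ...], ...] | None = None
        self._hash: int | None = None

    # -- construction helpers ------------------------------------------------

    @classmethod
    def identity(cls, n: int) -> "Mapping":
        return cls(range(n))

    @classmethod
    def from_cycles(cls, cycles: Iterable[Sequence[int]], n: int) -> "Mapping":
        """Build a permutation of ``{0..n-1}`` from disjoint cycles."""
        image = list(range(n))
        touched = [False] * n
        for cyc in cycles:
            for i, x in enumerate(cyc):
                if not 0 <= x < n:
                    raise ValidationError(f"symbol {x} outside ground set 0..{n - 1}")
                if touched[x]:
                    raise ValidationError(f"cycles are not disjoint at symbol {x}")
                touched[x] = True
                image[x] = cyc[(i + 1) % len(cyc)]
        return cls(image)

    # -- basic protocol ------------------------------------------------------

    def __call__(self, x: int) -> int:
        return self.image[x]

    def __len__(self) -> int:
        return len(self.image)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Mapping) and self.image == other.image

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash(self.image)
        return self._hash

    def __repr__(self) -> str:
        return f"Mapping({cycle_string(self)})"

    # -- group operations ----------------------------------------------------

    def inverse(self) -> "Mapping":
        inv = [0] * len(self.image)
        for x, y in enumerate(self.image):
            inv[y] = x
        return Mapping(inv)

    def __mul__(self, other: "Mapping") -> "Mapping":
        """``(self * other)(x) == self(other(x))``."""
        if len(self.image) != len(other.image):
            raise ValidationError(
                f"ground-set mismatch: {len(self.image)} vs {len(other.image)}"
            )
        s = self.image
        return Mapping(tuple(s[y] for y in other.image))

    # -- structure -----------------------------------------------------------

    @property
    def cycles(self) -> tuple[tuple[int, ...], ...]:
        """Disjoint-cycle decomposition, including 1-cycles.

        Each cycle is rotated to start at its smallest symbol; cycles are
        ordered by that symbol, so the decomposition is canonical.
        """
        if self._cycles is None:
            img = self.image
            seen = bytearray(len(img))
            out = []
            for start in range(len(img)):
                if seen[start]:
                    continue
                cyc = [start]
                seen[start] = 1
                x = img[start]
                while x != start:
                    cyc.append(x)
                    seen[x] = 1
                    x = img[x]
                out.append(tuple(cyc))
            self._cycles = tuple(out)
        return self._cycles

    def nontrivial_cycles(self) -> tuple[tuple[int, ...], ...]:
        return tuple(c for c in self.cycles if len(c) > 1)

    @property
    def c_odd(self) -> int:
        """Number of odd-length cycles, 1-cycles included."""
        return sum(1 for c in self.cycles if len(c) % 2 == 1)

    @property
    def support(self) -> frozenset[int]:
        return frozenset(x for x, y in enumerate(self.image) if x != y)

    def is_identity(self) -> bool:
        return all(x == y for x, y in enumerate(self.image))

    @property
    def is_even(self) -> bool:
        # parity = sum over cycles of (length - 1)
        return sum(len(c) - 1 for c in self.cycles) % 2 == 0


def compose(alpha: Mapping, beta: Mapping) -> Mapping:
    """Product ``alpha * beta`` mapping ``x`` to ``alpha(beta(x))``."""
    return alpha * beta


def disjoint_cycles(alpha: Mapping) -> tuple[tuple[int, ...], ...]:
    return alpha.cycles


def three_norm(alpha: Mapping) -> int:
    """Minimum number of 3-cycles whose product is ``alpha``.

    Defined for even permutations only; equals ``(N - c_odd(alpha)) / 2``
    where ``N`` is the ground-set size.
    """
    if not alpha.is_even:
        raise ValidationError("3-norm is undefined for odd permutations")
    return (len(alpha) - alpha.c_odd) // 2


def cycle_string(alpha: Mapping, keep_fixed: bool = False) -> str:
    """Render in cycle notation, e.g. ``"(0 3)(1 6 8)"``; fixed points dropped."""
    cycles = alpha.cycles if keep_fixed else alpha.nontrivial_cycles()
    if not cycles:
        return "()"
    return "".join("(" + " ".join(map(str, c)) + ")" for c in cycles)


# ---------------------------------------------------------------------------
# ThreeCycle
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class ThreeCycle:
    """An applicable-3-cycle candidate ``(a b c)``.

    Stored in canonical rotation (smallest symbol first), so that the three
    rotations of the same cycle compare equal while ``(a b c) != (a c b)``.
    The default ordering (lexicographic on the canonical triple) is the
    deterministic iteration order used throughout the package.
    """

    a: int
    b: int
    c: int

    def __init__(self, a: int, b: int, c: int):
        if len({a, b, c}) != 3:
            raise ValidationError(f"3-cycle symbols must be distinct: ({a} {b} {c})")
        if b < a and b < c:
            a, b, c = b, c, a
        elif c < a and c < b:
            a, b, c = c, a, b
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)

    @property
    def symbols(self) -> tuple[int, int, int]:
        return (self.a, self.b, self.c)

    def inverse(self) -> "ThreeCycle":
        return ThreeCycle(self.a, self.c, self.b)

    def as_mapping(self, n_ground: int) -> Mapping:
        return Mapping.from_cycles([self.symbols], n_ground)

    def __str__(self) -> str:
        return f"({self.a} {self.b} {self.c})"


# ---------------------------------------------------------------------------
# ChromosomeCycle
# ---------------------------------------------------------------------------


class ChromosomeCycle:
    """The ``(n+1)``-cycle ``(0 p1 .. pn)`` modelling a chromosome.

    ``symbols`` holds the cyclic order linearly in canonical rotation
    (starting at 0); a position index makes cyclic-order queries O(1).
    """

    __slots__ = ("symbols", "_pos", "_hash")

    def __init__(self, symbols: Sequence[int]):
        syms = tuple(symbols)
        if not syms or syms[0] != 0:
            raise ValidationError("chromosome cycle must start at symbol 0")
        seen = bytearray(len(syms))
        for s in syms:
            if not 0 <= s < len(syms):
                raise ValidationError(f"symbol {s} out of range 0..{len(syms) - 1}")
            if seen[s]:
                raise ValidationError(f"duplicate symbol {s}")
            seen[s] = 1
        self.symbols = syms
        pos = [0] * len(syms)
        for i, s in enumerate(syms):
            pos[s] = i
        self._pos = tuple(pos)
        self._hash: int | None = None

    # -- construction --------------------------------------------------------

    @classmethod
    def from_one_line(cls, p: Sequence[int]) -> "ChromosomeCycle":
        """Chromosome from one-line notation ``[p1 .. pn]`` over ``1..n``."""
        p = tuple(p)
        n = len(p)
        if n == 0:
            raise ValidationError("empty permutation")
        seen = bytearray(n + 1)
        for s in p:
            if not 1 <= s <= n:
                raise ValidationError(f"symbol {s} out of range 1..{n}")
            if seen[s]:
                raise ValidationError(f"duplicate symbol {s}")
            seen[s] = 1
        return cls((0,) + p)

    @property
    def n(self) -> int:
        """Genome length (number of non-zero symbols)."""
        return len(self.symbols) - 1

    def one_line(self) -> tuple[int, ...]:
        return self.symbols[1:]

    # -- protocol ------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ChromosomeCycle) and self.symbols == other.symbols

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash(self.symbols)
        return self._hash

    def __repr__(self) -> str:
        return "ChromosomeCycle((" + " ".join(map(str, self.symbols)) + "))"

    # -- cycle queries -------------------------------------------------------

    def position(self, x: int) -> int:
        """Index of ``x`` in the canonical linear storage of the cycle."""
        try:
            return self._pos[x]
        except IndexError:
            raise ValidationError(f"symbol {x} not in chromosome") from None

    def successor(self, x: int) -> int:
        """Next symbol after ``x`` in cyclic order (the image pi_bar(x))."""
        return self.symbols[(self.position(x) + 1) % len(self.symbols)]

    def in_cyclic_order(self, a: int, b: int, c: int) -> bool:
        """True iff, reading the cycle from ``a``, ``b`` occurs before ``c``."""
        m = len(self.symbols)
        pa = self.position(a)
        rb = (self.position(b) - pa) % m
        rc = (self.position(c) - pa) % m
        if rb == 0 or rc == 0 or rb == rc:
            raise ValidationError("cyclic-order query needs three distinct symbols")
        return rb < rc

    # -- group view ----------------------------------------------------------

    def as_mapping(self) -> Mapping:
        return Mapping.from_cycles([self.symbols], len(self.symbols))

    def inverse(self) -> "ChromosomeCycle":
        """Chromosome cycle read in the reverse cyclic order."""
        return ChromosomeCycle((0,) + tuple(reversed(self.symbols[1:])))


def identity_chromosome(n: int) -> ChromosomeCycle:
    """The sorted chromosome ``iota_bar = (0 1 .. n)``."""
    if n < 1:
        raise ValidationError("genome length must be >= 1")
    return ChromosomeCycle(range(n + 1))


def chromosome_from_one_line(p: Sequence[int]) -> ChromosomeCycle:
    return ChromosomeCycle.from_one_line(p)


def inverse(x: "ChromosomeCycle | Mapping"):
    return x.inverse()


# ---------------------------------------------------------------------------
# Residual permutation and moves
# ---------------------------------------------------------------------------


def residual(pi_bar: ChromosomeCycle) -> Mapping:
    """The residual ``iota_bar * pi_bar**-1`` driving all structure analysis.

    Its disjoint cycles play the role the cycle graph plays in the classical
    formulation; it is always an even permutation, so its 3-norm is defined.
    Computed directly: ``x -> iota_bar(pi_bar_inverse(x))`` where the inverse
    of ``pi_bar`` maps each symbol to its cyclic predecessor.
    """
    syms = pi_bar.symbols
    m = len(syms)
    image = [0] * m
    # pi_bar_inv(symbol at i) = symbol at i-1; iota_bar adds 1 mod m.
    for i, s in enumerate(syms):
        image[s] = (syms[i - 1] + 1) % m
    return Mapping(image)


def chromosome_from_residual(sigma: Mapping, n: int) -> ChromosomeCycle:
    """Inverse of :func:`residual`: the chromosome with ``residual == sigma``.

    Solves ``sigma = iota_bar * pi_bar**-1`` for ``pi_bar = sigma**-1 *
    iota_bar``; fails if that product is not a single ``(n+1)``-cycle (not
    every even permutation is realizable as a residual).
    """
    if len(sigma) != n + 1:
        raise ValidationError(f"sigma must act on 0..{n}")
    if not sigma.is_even:
        raise ValidationError("a residual permutation is always even")
    inv = sigma.inverse()
    m = n + 1
    syms = [0]
    x = 0
    for _ in range(n):
        x = inv((x + 1) % m)  # pi_bar(x) = sigma_inv(iota_bar(x))
        syms.append(x)
    if len(set(syms)) != m or inv((syms[-1] + 1) % m) != 0:
        raise ValidationError(
            f"sigma**-1 * iota_bar is not a single {m}-cycle; "
            "sigma is not realizable as a residual"
        )
    return ChromosomeCycle(syms)


def is_applicable(tau: ThreeCycle, pi_bar: ChromosomeCycle) -> bool:
    """True iff the symbols of ``tau`` occur in ``pi_bar`` in the same cyclic
    order, i.e. the product ``tau * pi_bar`` is again a single cycle."""
    return pi_bar.in_cyclic_order(tau.a, tau.b, tau.c)


def applicable_orientation(symbols: Iterable[int], pi_bar: ChromosomeCycle) -> ThreeCycle:
    """The unique applicable 3-cycle on a 3-symbol set.

    Any three distinct symbols occur around ``pi_bar`` in exactly one cyclic
    order, so exactly one of the two 3-cycles on them is applicable.
    """
    a, b, c = symbols
    if pi_bar.in_cyclic_order(a, b, c):
        return ThreeCycle(a, b, c)
    return ThreeCycle(a, c, b)


def apply_3cycle(tau: ThreeCycle, pi_bar: ChromosomeCycle) -> ChromosomeCycle:
    """The transposition ``tau * pi_bar`` (blocks cut and pasted).

    Refuses non-applicable ``tau``: the product would split into several
    cycles and no longer represent a chromosome.
    """
    if not is_applicable(tau, pi_bar):
        raise ValidationError(f"{tau} is not applicable: product is not a single cycle")
    syms = pi_bar.symbols
    m = len(syms)
    tau_map = {tau.a: tau.b, tau.b: tau.c, tau.c: tau.a}
    image = [0] * m
    for i, s in enumerate(syms):
        y = syms[(i + 1) % m]
        image[s] = tau_map.get(y, y)
    out = [0]
    x = image[0]
    while x != 0:
        out.append(x)
        x = image[x]
    return ChromosomeCycle(out)


def apply_sequence(taus: Iterable[ThreeCycle], pi_bar: ChromosomeCycle) -> ChromosomeCycle:
    for tau in taus:
        pi_bar = apply_3cycle(tau, pi_bar)
    return pi_bar


def classify_move(tau: ThreeCycle, pi_bar: ChromosomeCycle) -> int:
    """Change in the residual's odd-cycle count caused by applying ``tau``.

    Applying ``tau`` to the chromosome multiplies the residual by
    ``tau**-1`` on the right; the resulting change in ``c_odd`` is always in
    ``{-2, 0, +2}``.  A ``+2``-move is the productive case: it lowers the
    3-norm of the residual (the sorting lower bound) by one.
    """
    if not is_applicable(tau, pi_bar):
        raise ValidationError(f"{tau} is not applicable")
    sigma = residual(pi_bar)
    return _move_delta(sigma, tau)


def _move_delta(sigma: Mapping, tau: ThreeCycle) -> int:
    """``c_odd(sigma * tau**-1) - c_odd(sigma)`` in O(1) via cycle structure.

    Only the cycles of ``sigma`` meeting ``tau``'s support matter: the
    product either splits one cycle into three, redistributes two cycles
    into two, or merges three cycles into one.
    """
    info = _cycle_info(sigma)
    return _move_delta_indexed(info, tau)


def _cycle_info(sigma: Mapping):
    """Per-symbol (cycle id, index within cycle, cycle length) table."""
    cid = {}
    idx = {}
    clen = {}
    for k, cyc in enumerate(sigma.cycles):
        clen[k] = len(cyc)
        for i, x in enumerate(cyc):
            cid[x] = k
            idx[x] = i
    return cid, idx, clen


def _move_delta_indexed(info, tau: ThreeCycle) -> int:
    cid, idx, clen = info
    a, b, c = tau.symbols
    ka, kb, kc = cid[a], cid[b], cid[c]
    odd = lambda v: v % 2

    if ka == kb == kc:
        k = clen[ka]
        # arc lengths around the sigma-cycle from a to b, b to c, c to a
        d_ab = (idx[b] - idx[a]) % k
        d_bc = (idx[c] - idx[b]) % k
        d_ca = (idx[a] - idx[c]) % k
        if d_ab + d_bc + d_ca != k:
            # (a, b, c) not in sigma-cyclic order: the cycle does not split
            return 0
        return odd(d_ab) + odd(d_bc) + odd(d_ca) - odd(k)

    if ka != kb and kb != kc and ka != kc:
        k1, k2, k3 = clen[ka], clen[kb], clen[kc]
        return odd(k1 + k2 + k3) - odd(k1) - odd(k2) - odd(k3)

    # exactly two symbols share a cycle; rotate tau so u, v share and w is apart
    if ka == kb:
        u, v, w = a, b, c
    elif kb == kc:
        u, v, w = b, c, a
    else:  # kc == ka
        u, v, w = c, a, b
    k1 = clen[cid[u]]
    k2 = clen[cid[w]]
    d_uv = (idx[v] - idx[u]) % k1
    return odd(d_uv) + odd(k1 - d_uv + k2) - odd(k1) - odd(k2)


# ---------------------------------------------------------------------------
# Bounds
# ---------------------------------------------------------------------------


def lower_bound(pi_bar: ChromosomeCycle) -> int:
    """Sorting lower bound: the 3-norm ``(n + 1 - c_odd(residual)) / 2``.

    No sequence of applicable 3-cycles shorter than the residual's 3-norm can
    sort the chromosome, since each transposition is a single 3-cycle factor.
    """
    return three_norm(residual(pi_bar))


def f_upper(m: int) -> int:
    """``f(m) = 11*floor(m/8) + floor(3*(m mod 8)/2)``.

    Worst-case move budget to clear a residual of 3-norm ``m``: blocks of
    norm 8 cost at most 11 moves (an 11/8-sequence), the remainder is cleared
    at the 3/2 rate of (3,2)-sequences.
    """
    if m < 0:
        raise ValidationError("norm must be non-negative")
    return 11 * (m // 8) + (3 * (m % 8)) // 2


def upper_bound(pi_bar: ChromosomeCycle) -> int:
    """Distance upper bound ``f(three_norm(residual))``, valid for every
    chromosome (certified constructively by the solver)."""
    return f_upper(lower_bound(pi_bar))


def diameter_upper_bound(n: int) -> int:
    """Upper bound on the transposition diameter of genomes of length ``n``:
    ``11*floor(n/16) + floor(3*(n mod 16)/4)``."""
    if n < 1:
        raise ValidationError("genome length must be >= 1")
    return 11 * (n // 16) + (3 * (n % 16)) // 4


# ---------------------------------------------------------------------------
# Text formats
# ---------------------------------------------------------------------------


def parse_one_line(text: str) -> tuple[int, ...]:
    """Parse a whitespace-separated one-line permutation ``1..n``."""
    try:
        vals = tuple(int(tok) for tok in text.split())
    except ValueError as exc:
        raise ValidationError(f"malformed permutation line: {text!r}") from exc
    if not vals:
        raise ValidationError("empty permutation line")
    n = len(vals)
    seen = set()
    for v in vals:
        if not 1 <= v <= n:
            raise ValidationError(f"symbol {v} out of range 1..{n}")
        if v in seen:
            raise ValidationError(f"duplicate symbol {v}")
        seen.add(v)
    return vals


def iter_permutation_lines(lines: Iterable[str]) -> Iterator[tuple[int, tuple[int, ...]]]:
    """Yield ``(line_number, permutation)`` skipping blanks and '#' comments."""
    for ln, raw in enumerate(lines, start=1):
        text = raw.strip()
        if not text or text.startswith("#"):
            continue
        try:
            yield ln, parse_one_line(text)
        except ValidationError as exc:
            raise ValidationError(f"line {ln}: {exc}") from None
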