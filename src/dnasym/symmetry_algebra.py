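"""Composite pair observables and the R/C symmetry algebra.

A pair observable ``Y = (X_A, X_B; ell)`` requires pattern ``X_A`` and
pattern ``X_B`` to co-occur at separation scale ``ell``.  Two elementary
transformations act on pairs:

* ``R`` swaps the two patterns: ``(X_A, X_B; ell) -> (X_B, X_A; ell)``;
* ``C`` reverse-complements the first pattern only.

Both are involutions and they do not commute.  ``CRC`` maps Y to its full
reverse complement ``(revcomp(X_B), revcomp(X_A); ell)`` — the extended
Chargaff transformation.  A symmetry is a set of words over {R, C}; its
closure set for a reference Y collects every observable reachable by
repeatedly applying the generator words.  The four registered symmetries
form the nested hierarchy S1 ⊂ S2 ⊂ S3 and S4 ⊂ S3:

========  ============  generic closure size
S1        {CRC}         2
S2        {CRC, R}      4
S3        {R, C}        8
S4        {RCR, C}      4
========  ============  ======================
"""

from __future__ import annotations

from dataclasses import dataclass

from .observables import GappedPattern, revcomp_pattern


@dataclass(frozen=True)
class PairObservable:
    """Two gapped patterns at a separation scale; equality is componentwise."""

    first: GappedPattern
    second: GappedPattern
    separation: int

    def __post_init__(self):
        if self.separation < 1:
            raise ValueError("separation must be >= 1")

    def __str__(self) -> str:
        return f"({self.first},{self.second};{self.separation})"


@dataclass(frozen=True)
class SymmetryDef:
    """A named symmetry: a set of generator words over {R, C}."""

    name: str
    generators: frozenset[str]

    def __post_init__(self):
        for word in self.generators:
            if not word or any(c not in "RC" for c in word):
                raise ValueError(f"bad generator word {word!r}")


#: the fixed registry of the four nested symmetries
SYMMETRIES: dict[str, SymmetryDef] = {
    "S1": SymmetryDef("S1", frozenset({"CRC"})),
    "S2": SymmetryDef("S2", frozenset({"CRC", "R"})),
    "S3": SymmetryDef("S3", frozenset({"R", "C"})),
    "S4": SymmetryDef("S4", frozenset({"RCR", "C"})),
}


def pair_to_pattern(Y: PairObservable, convention: str = "formula") -> GappedPattern:
    """Flatten a pair observable into a single gapped pattern.

    Under the default ``"formula"`` convention the middle gap equals the
    separation scale, so for two dinucleotides the second pattern starts
    ``ell + 1`` positions after the first.  Under the ``"table1"`` convention
    the middle gap is ``ell + 1``: a separation of ell means ell arbitrary
    positions *between* the last symbol of X_A and the first symbol of X_B.
    """
    if convention == "formula":
        middle = Y.separation
    elif convention == "table1":
        middle = Y.separation + 1
    else:
        raise ValueError(f"unknown separation convention {convention!r}")
    symbols = Y.first.symbols + Y.second.symbols
    gaps = Y.first.gaps + (middle,) + Y.second.gaps
    return GappedPattern(symbols, gaps)


def transform_R(Y: PairObservable) -> PairObservable:
    """Swap the two patterns of the pair (involution)."""
    return PairObservable(Y.second, Y.first, Y.separation)


def transform_C(Y: PairObservable) -> PairObservable:
    """Reverse-complement the first pattern of the pair (involution)."""
    return PairObservable(revcomp_pattern(Y.first), Y.second, Y.separation)


_LETTERS = {"R": transform_R, "C": transform_C}


def apply_word(word: str, Y: PairObservable) -> PairObservable:
    """Apply a composition word over {R, C} to Y.

    Letters act right-to-left (standard operator composition): the rightmost
    transformation is applied first, so ``"CR"`` means C after R.
    """
    if not word:
        raise ValueError("empty transformation word")
    for letter in reversed(word):
        try:
            Y = _LETTERS[letter](Y)
        except KeyError:
            raise ValueError(f"unknown transformation letter {letter!r}") from None
    return Y


def closure(S: SymmetryDef, Y_ref: PairObservable) -> frozenset[PairObservable]:
    """Smallest set containing Y_ref closed under the generator words of S.

    Breadth-first closure with set semantics; always contains Y_ref and is
    finite (at most 8 elements for dinucleotide pairs).
    """
    seen = {Y_ref}
    frontier = [Y_ref]
    while frontier:
        nxt = []
        for Y in frontier:
            for word in S.generators:
                Z = apply_word(word, Y)
                if Z not in seen:
                    seen.add(Z)
                    nxt.append(Z)
        frontier = nxt
    return frozenset(seen)
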