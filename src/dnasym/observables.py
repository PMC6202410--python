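"""Gapped-pattern observables and their occurrence frequencies.

An observable ``X = (symbols, gaps)`` prescribes k+1 symbols together with
the k pairwise distances (gaps) between consecutive ones; a contiguous
oligonucleotide is the special case of all gaps equal to 1.  Its frequency
``P(X)`` is the fraction of the ``N' = N - size(X) + 1`` start positions of a
sequence at which every prescribed symbol matches.  The reverse complement of
an observable complements and reverses the symbols and reverses the gap
vector, so that an occurrence of X on one strand is an occurrence of
``revcomp(X)`` on the other; Chargaff's second parity rule, extended to
arbitrary observables, is the statement P(X) ≈ P(revcomp(X)) on a single
strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction

from .sequence_io import ALPHABET, Sequence

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class GappedPattern:
    """An observable: symbols at prescribed pairwise distances.

    ``gaps[i]`` is the distance between ``symbols[i]`` and ``symbols[i+1]``;
    gap 1 means adjacent.  ``GappedPattern(("A", "C", "G"), (1, 2))`` matches
    A at offset 0, C at offset 1 and G at offset 3.
    """

    symbols: tuple[str, ...]
    gaps: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "symbols", tuple(self.symbols))
        object.__setattr__(self, "gaps", tuple(int(g) for g in self.gaps))
        if len(self.symbols) == 0:
            raise ValueError("pattern needs at least one symbol")
        if len(self.gaps) != len(self.symbols) - 1:
            raise ValueError("need exactly len(symbols) - 1 gaps")
        if any(s not in ALPHABET for s in self.symbols):
            raise ValueError(f"symbols must be in {ALPHABET}")
        if any(g < 1 for g in self.gaps):
            raise ValueError("gaps must be >= 1")

    @property
    def size(self) -> int:
        """Span of the pattern in base pairs: sum of gaps plus one."""
        return sum(self.gaps) + 1

    @property
    def offsets(self) -> tuple[int, ...]:
        """Offset of each symbol from the pattern start (first is 0)."""
        out, acc = [0], 0
        for g in self.gaps:
            acc += g
            out.append(acc)
        return tuple(out)

    @classmethod
    def from_string(cls, text: str) -> "GappedPattern":
        """Parse a pattern literal.

        ``"A1C2G"`` means symbols A, C, G with gaps 1 and 2.  A literal with
        no digits at all, e.g. ``"ACT"``, is shorthand for a contiguous
        oligonucleotide (all gaps 1); otherwise a gap value is mandatory
        between every pair of letters.
        """
        text = text.strip().upper()
        if not text:
            raise ValueError("empty pattern literal")
        if text.isalpha():
            return cls(tuple(text), (1,) * (len(text) - 1))
        tokens = re.findall(r"[A-Z]|\d+", text)
        if "".join(tokens) != text:
            raise ValueError(f"cannot parse pattern literal {text!r}")
        symbols, gaps = [], []
        expect_symbol = True
        for tok in tokens:
            if tok.isdigit():
                if expect_symbol:
                    raise ValueError(f"misplaced gap in {text!r}")
                gaps.append(int(tok))
                expect_symbol = True
            else:
                if not expect_symbol:
                    raise ValueError(
                        f"missing gap between letters in {text!r} "
                        "(gaps are mandatory when any digit is present)"
                    )
                symbols.append(tok)
                expect_symbol = False
        if expect_symbol:
            raise ValueError(f"pattern literal {text!r} ends with a gap")
        return cls(tuple(symbols), tuple(gaps))

    def to_string(self) -> str:
        if all(g == 1 for g in self.gaps):
            return "".join(self.symbols)
        parts = [self.symbols[0]]
        for g, s in zip(self.gaps, self.symbols[1:]):
            parts.append(str(g))
            parts.append(s)
        return "".join(parts)

    def __str__(self) -> str:
        return self.to_string()


@dataclass(frozen=True)
class PatternFrequency:
    """An exact occurrence count over an exact number of windows."""

    count: int
    windows: int

    @property
    def frequency(self) -> float:
        return self.count / self.windows if self.windows > 0 else float("nan")

    @property
    def fraction(self) -> Fraction | None:
        """Exact rational frequency, or None when no window fits."""
        return Fraction(self.count, self.windows) if self.windows > 0 else None

    @property
    def defined(self) -> bool:
        return self.windows > 0


def pattern_size(X: GappedPattern) -> int:
    return X.size


def count_pattern(seq: Sequence, X: GappedPattern) -> PatternFrequency:
    """Count occurrences of ``X`` over all start positions of ``seq``.

    Every window is examined, so overlapping occurrences all count.  When the
    pattern does not fit (size > N) the result has ``windows == 0`` and an
    undefined frequency.
    """
    codes = seq.codes
    n_windows = seq.N - X.size + 1
    if n_windows <= 0:
        return PatternFrequency(0, 0)
    sym_codes = [ALPHABET.index(s) for s in X.symbols]
    offsets = X.offsets
    mask = codes[0:n_windows] == sym_codes[0]
    for off, sc in zip(offsets[1:], sym_codes[1:]):
        mask = mask & (codes[off : off + n_windows] == sc)
    return PatternFrequency(int(mask.sum()), n_windows)


def revcomp_sequence(seq: Sequence) -> Sequence:
    """Reverse complement of a cleaned sequence (an involution)."""
    return Sequence.from_codes(3 - seq.codes[::-1], label=seq.label)


def revcomp_pattern(X: GappedPattern) -> GappedPattern:
    """Reverse complement of an observable: symbols complemented and
    reversed, gaps reversed.  Preserves the pattern size; involution."""
    symbols = tuple(_COMPLEMENT[s] for s in reversed(X.symbols))
    return GappedPattern(symbols, tuple(reversed(X.gaps)))
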