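"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from dnasym.observables import GappedPattern
from dnasym.sequence_io import ALPHABET, Sequence, clean_sequence


def make_seq(text: str, label: str = "test") -> Sequence:
    seq, _ = clean_sequence(text)
    return Sequence(seq.symbols, label=label)


def naive_count(text: str, pattern: GappedPattern) -> tuple[int, int]:
    """Position-by-position scanning oracle for pattern counting.

    Deliberately independent of the vectorized implementation: walks every
    window start and checks each prescribed symbol by string indexing.
    """
    offsets = pattern.offsets
    n_windows = len(text) - pattern.size + 1
    if n_windows <= 0:
        return 0, 0
    count = 0
    for i in range(n_windows):
        if all(text[i + off] == sym for off, sym in zip(offsets, pattern.symbols)):
            count += 1
    return count, n_windows


def random_sequence(rng: np.random.Generator, length: int, label: str = "rand") -> Sequence:
    text = "".join(rng.choice(list(ALPHABET), size=length))
    return make_seq(text, label)


def random_pattern(rng: np.random.Generator, max_symbols: int = 4,
                   max_gap: int = 8) -> GappedPattern:
    k = int(rng.integers(1, max_symbols + 1))
    symbols = tuple(rng.choice(list(ALPHABET), size=k))
    gaps = tuple(int(g) for g in rng.integers(1, max_gap + 1, size=k - 1))
    return GappedPattern(symbols, gaps)


@pytest.fixture
def worked_seq() -> Sequence:
    """The 16-mer used in the worked counting example."""
    return make_seq("GGACCGGCCACAGGAA", label="worked")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
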