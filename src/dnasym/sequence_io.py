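"""Reading, cleaning and writing nucleotide sequences.

Sequences are plain strings over the alphabet {A, C, G, T} together with a
free-text label.  Real chromosome files contain assembly gaps (runs of ``N``)
and IUPAC ambiguity codes; :func:`clean_sequence` deletes every character
outside the four-letter alphabet (splicing the sequence, not segmenting it)
and reports the removed fraction, which is the preprocessing applied before
any counting.  Soft-masked lowercase bases are uppercased *before* filtering,
so masked a/c/g/t are retained.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

ALPHABET = "ACGT"

#: byte -> 2-bit code (A=0, C=1, G=2, T=3); 255 marks a non-ACGT byte
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate(ALPHABET):
    _ENCODE[ord(_ch)] = _i

_DECODE = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)


@dataclass
class Sequence:
    """A nucleotide sequence with a label.

    ``symbols`` may contain non-ACGT characters straight after FASTA parsing;
    numeric access through :attr:`codes` requires a cleaned sequence.
    """

    symbols: str
    label: str = ""
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def N(self) -> int:
        """Number of stored symbols."""
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def codes(self) -> np.ndarray:
        """2-bit codes (A=0, C=1, G=2, T=3) as a uint8 array.

        Raises ``ValueError`` if the sequence has not been cleaned.
        """
        if self._codes is None:
            raw = np.frombuffer(self.symbols.encode("ascii"), dtype=np.uint8)
            codes = _ENCODE[raw]
            if codes.size and codes.max() == 255:
                bad = chr(int(raw[int(np.argmax(codes == 255))]))
                raise ValueError(
                    f"sequence {self.label!r} contains non-ACGT symbol {bad!r}; "
                    "run clean_sequence first"
                )
            self._codes = codes
        return self._codes

    @classmethod
    def from_codes(cls, codes: np.ndarray, label: str = "") -> "Sequence":
        codes = np.asarray(codes, dtype=np.uint8)
        symbols = _DECODE[codes].tobytes().decode("ascii")
        return cls(symbols, label, _codes=codes)

    def is_clean(self) -> bool:
        raw = np.frombuffer(self.symbols.encode("ascii"), dtype=np.uint8)
        return bool((_ENCODE[raw] != 255).all()) if raw.size else True


def read_fasta(path, record_policy: str = "per-record") -> list[Sequence]:
    """Parse a FASTA file into uppercased, *uncleaned* sequences.

    Parameters
    ----------
    path:
        Path to a FASTA file.
    record_policy:
        ``"per-record"`` returns one :class:`Sequence` per record (the default,
        one analysis per chromosome), ``"first"`` returns only the first
        record, ``"concatenate"`` joins all records in file order into a
        single sequence labelled after the file.
    """
    if record_policy not in ("first", "concatenate", "per-record"):
        raise ValueError(f"unknown record_policy {record_policy!r}")
    records = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records.append(Sequence(str(rec.seq).upper(), label=rec.id))
            if record_policy == "first":
                break
    if not records:
        raise ValueError(f"no records in {path}")
    if record_policy == "concatenate" and len(records) > 1:
        joined = "".join(r.symbols for r in records)
        return [Sequence(joined, label=os.path.basename(str(path)))]
    return records[:1] if record_policy == "first" else records


def clean_sequence(raw) -> tuple[Sequence, float]:
    """Uppercase and strip every non-ACGT character from ``raw``.

    Accepts a string or a :class:`Sequence`; returns the cleaned sequence and
    the fraction of characters removed (0.0 for empty input).  Retained
    symbols keep their relative order.  Total function: never raises on
    content.
    """
    if isinstance(raw, Sequence):
        label, text = raw.label, raw.symbols
    else:
        label, text = "", str(raw)
    text = text.upper()
    arr = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[arr]
    keep = codes != 255
    kept = codes[keep]
    removed_fraction = 1.0 - kept.size / arr.size if arr.size else 0.0
    return Sequence.from_codes(kept, label=label), removed_fraction


def clean_and_split(raw, min_gap_run: int) -> tuple[list[Sequence], float]:
    """Clean like :func:`clean_sequence` but split at long non-ACGT runs.

    Runs of at least ``min_gap_run`` consecutive non-ACGT characters (after
    uppercasing) become segment boundaries instead of being spliced over —
    useful when counting windows should not span assembly gaps.  Shorter
    runs are spliced as usual.  Returns the non-empty segments (labelled
    ``label/1``, ``label/2``, ...) and the overall removed fraction.
    """
    if min_gap_run < 1:
        raise ValueError("min_gap_run must be >= 1")
    if isinstance(raw, Sequence):
        label, text = raw.label, raw.symbols
    else:
        label, text = "", str(raw)
    text = text.upper()
    arr = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    bad = _ENCODE[arr] == 255
    removed_fraction = bad.sum() / arr.size if arr.size else 0.0
    # boundaries of maximal non-ACGT runs
    edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
    segments, prev = [], 0
    for start, stop in edges.reshape(-1, 2):
        if stop - start >= min_gap_run:
            segments.append((prev, start))
            prev = stop
    segments.append((prev, arr.size))
    out = []
    for i, (a, b) in enumerate(segments, start=1):
        piece, _ = clean_sequence(text[a:b])
        if piece.N:
            piece.label = f"{label}/{i}" if label else f"segment/{i}"
            out.append(piece)
    return out, float(removed_fraction)


def write_fasta(seq: Sequence, path, line_width: int = 60) -> None:
    """Write ``seq`` as a single FASTA record wrapped at ``line_width``."""
    if line_width < 1:
        raise ValueError("line_width must be positive")
    with open(path, "w") as handle:
        handle.write(f">{seq.label or 'sequence'}\n")
        s = seq.symbols
        for i in range(0, len(s), line_width):
            handle.write(s[i : i + line_width] + "\n")
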