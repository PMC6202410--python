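"""Normalized cross-correlations z(ell) of dinucleotide pairs over scales.

For a pair observable ``Y = (X_A, X_B; ell)`` the cross-correlation

    z(ell) = P(X_A, X_B; ell) / (P(X_A) P(X_B))

compares the joint occurrence frequency with what independence would give;
deviations from z = 1 are signatures of structure (correlations).  The bulk
scanner computes z for all 256 ordered dinucleotide pairs on a dyadic grid
of scales ell = 2^i, counting the 256 joint occurrences at each scale in a
single pass over the sequence via a histogram of position-wise dinucleotide
codes.  Marginals are frequencies over the whole sequence (N - 1 windows for
a dinucleotide).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .observables import GappedPattern, PatternFrequency, count_pattern
from .sequence_io import ALPHABET, Sequence
from .symmetry_algebra import PairObservable, pair_to_pattern

logger = logging.getLogger(__name__)

#: the 16 dinucleotides in code order (AA, AC, AG, AT, CA, ...)
DINUCLEOTIDES: list[str] = [a + b for a in ALPHABET for b in ALPHABET]

#: statistical floor: scales whose composite has fewer windows are dropped
MIN_WINDOWS = 1000


def dinucleotide_index(dinuc: str) -> int:
    """Code of a dinucleotide in the 0..15 ordering used by the scanner."""
    return ALPHABET.index(dinuc[0]) * 4 + ALPHABET.index(dinuc[1])


def pair_index(a: str, b: str) -> int:
    """Code of an ordered dinucleotide pair in the 0..255 ordering."""
    return dinucleotide_index(a) * 16 + dinucleotide_index(b)


def dinucleotide_pattern(dinuc: str) -> GappedPattern:
    return GappedPattern(tuple(dinuc), (1,))


@dataclass(frozen=True)
class ScaleGrid:
    """Dyadic grid of separation scales ell = 2^i."""

    exponents: tuple[int, ...] = tuple(range(25))

    def __post_init__(self):
        exps = tuple(int(e) for e in self.exponents)
        if len(exps) == 0:
            raise ValueError("empty scale grid")
        if any(e < 0 for e in exps) or any(b <= a for a, b in zip(exps, exps[1:])):
            raise ValueError("exponents must be nonnegative and strictly increasing")
        object.__setattr__(self, "exponents", exps)

    @property
    def scales(self) -> tuple[int, ...]:
        return tuple(2**e for e in self.exponents)


def _start_offset(separation: int, convention: str) -> int:
    """Offset between the start of X_A and the start of X_B (dinucleotides)."""
    if convention == "formula":
        return separation + 1
    if convention == "table1":
        return separation + 2
    raise ValueError(f"unknown separation convention {convention!r}")


@dataclass
class CorrelationTable:
    """z values for all 256 ordered dinucleotide pairs at each kept scale.

    Joint counts are stored as integers so that every z can be re-verified
    exactly; ``dropped`` records scales excluded because too few windows fit.
    """

    label: str
    convention: str
    joint_counts: dict[int, np.ndarray] = field(default_factory=dict)
    joint_windows: dict[int, int] = field(default_factory=dict)
    marginal_counts: np.ndarray | None = None
    marginal_windows: int = 0
    dropped: dict[int, str] = field(default_factory=dict)
    _z: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def scales(self) -> list[int]:
        return sorted(set(self.joint_counts) | set(self._z))

    def z_values(self, ell: int) -> np.ndarray:
        """z for all 256 pairs at scale ell, ordered by pair code; entries
        with a zero marginal or no windows are NaN."""
        if ell in self._z:
            return self._z[ell]
        if ell not in self.joint_counts:
            raise KeyError(f"scale {ell} not in table (dropped: {self.dropped.get(ell)})")
        counts = self.joint_counts[ell]
        nw = self.joint_windows[ell]
        p_joint = counts / nw if nw > 0 else np.full(256, np.nan)
        p_marg = self.marginal_counts / self.marginal_windows
        denom = np.repeat(p_marg, 16) * np.tile(p_marg, 16)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(denom > 0, p_joint / denom, np.nan)
        self._z[ell] = z
        return z

    def z(self, a: str, b: str, ell: int) -> float:
        return float(self.z_values(ell)[pair_index(a, b)])

    @classmethod
    def from_z(cls, z_by_scale: dict[int, np.ndarray], label: str = "synthetic",
               convention: str = "formula") -> "CorrelationTable":
        """Build a table directly from z arrays (no counts); used for nulls."""
        table = cls(label=label, convention=convention)
        for ell, z in z_by_scale.items():
            z = np.asarray(z, dtype=float)
            if z.shape != (256,):
                raise ValueError("need one z per ordered dinucleotide pair")
            table._z[int(ell)] = z
        return table

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (X_A, X_B, ell) with counts and z."""
        rows = []
        names_a = np.repeat(DINUCLEOTIDES, 16)
        names_b = np.tile(DINUCLEOTIDES, 16)
        p_marg = (
            self.marginal_counts / self.marginal_windows
            if self.marginal_counts is not None
            else np.full(16, np.nan)
        )
        for ell in self.scales:
            z = self.z_values(ell)
            counts = self.joint_counts.get(ell)
            nw = self.joint_windows.get(ell, 0)
            frame = pd.DataFrame(
                {
                    "seq_label": self.label,
                    "X_A": names_a,
                    "X_B": names_b,
                    "ell": ell,
                    "convention": self.convention,
                    "count": counts if counts is not None else -1,
                    "windows": nw,
                    "P_joint": counts / nw if counts is not None and nw else np.nan,
                    "P_A": np.repeat(p_marg, 16),
                    "P_B": np.tile(p_marg, 16),
                    "z": z,
                }
            )
            rows.append(frame)
        return pd.concat(rows, ignore_index=True)


def pair_frequency(seq: Sequence, Y: PairObservable,
                   convention: str = "formula") -> PatternFrequency:
    """Joint frequency of a pair observable: the flattened-pattern count."""
    return count_pattern(seq, pair_to_pattern(Y, convention))


def z_score(seq: Sequence, Y: PairObservable, convention: str = "formula") -> float:
    """Cross-correlation z for one pair observable.

    Marginals are computed over the whole sequence with their own window
    counts.  Returns NaN when a marginal is zero or no composite window fits.
    """
    joint = pair_frequency(seq, Y, convention)
    pa = count_pattern(seq, Y.first)
    pb = count_pattern(seq, Y.second)
    if not joint.defined or not pa.defined or not pb.defined:
        return float("nan")
    if pa.count == 0 or pb.count == 0:
        return float("nan")
    return joint.frequency / (pa.frequency * pb.frequency)


def scan_all_pairs(seq: Sequence, grid: ScaleGrid | None = None,
                   convention: str = "formula",
                   min_windows: int = MIN_WINDOWS) -> CorrelationTable:
    """Joint counts and z for all 256 ordered dinucleotide pairs per scale.

    At each scale the 256 joint counts are obtained in one pass as a
    histogram of ``16 * code(dinuc at i) + code(dinuc at i + offset)``; the
    integer counts equal a per-pair window scan exactly.  Scales with fewer
    than ``min_windows`` composite windows are dropped and logged.
    """
    if grid is None:
        grid = ScaleGrid()
    _start_offset(1, convention)  # validate convention early
    codes = seq.codes
    if seq.N < 2:
        raise ValueError("sequence too short for dinucleotide statistics")
    dinuc = (codes[:-1].astype(np.int64) << 2) | codes[1:]
    table = CorrelationTable(label=seq.label, convention=convention)
    table.marginal_counts = np.bincount(dinuc, minlength=16)
    table.marginal_windows = dinuc.size
    for ell in grid.scales:
        off = _start_offset(ell, convention)
        n_windows = seq.N - (off + 2) + 1
        if n_windows < min_windows:
            reason = f"only {max(n_windows, 0)} windows (< {min_windows})"
            table.dropped[ell] = reason
            logger.info("dropping scale %d for %s: %s", ell, seq.label, reason)
            continue
        joint = np.bincount((dinuc[:n_windows] << 4) | dinuc[off : off + n_windows],
                            minlength=256)
        table.joint_counts[ell] = joint
        table.joint_windows[ell] = n_windows
    if not table.joint_counts:
        raise ValueError("no scale in the grid fits the sequence")
    return table
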