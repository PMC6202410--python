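"""Symmetry indices I_S(ell) and detection of characteristic scales.

For a reference pair Y_ref and symmetry S, the distance

    d_ell(Y_ref; S) = (1/|S_S|) * sum_{Y in S_S(Y_ref)} (z_Y - z_ref)^2 / sigma(ell)^2

measures how much z varies inside the closure set of Y_ref, relative to the
spread sigma(ell) of z over all 256 ordered dinucleotide pairs.  Averaging
over every reference pair gives the symmetry index

    I_S(ell) = (1 / (2 |A|)) * sum_{Y_ref in A} d_ell(Y_ref; S),   |A| = 256.

I_S = 0 means the symmetry holds exactly at that scale (z constant within
every closure); for z varying as much within closures as across all pairs
the index approaches (|S_S| - 1)/|S_S| for non-degenerate closures.  A
symmetry is declared present at a scale when I_S <= 0.025, and the first
crossings of the four curves locate the characteristic scales L_D (domain),
L_S (same-type cluster) and L_M (macrostructure).
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlation_scan import DINUCLEOTIDES, CorrelationTable, dinucleotide_pattern, pair_index
from .symmetry_algebra import SYMMETRIES, PairObservable, SymmetryDef, closure

logger = logging.getLogger(__name__)

#: a symmetry is considered present at a scale when I_S is at or below this
PRESENCE_THRESHOLD = 0.025


def _dinuc_pair(a: str, b: str, separation: int = 1) -> PairObservable:
    return PairObservable(dinucleotide_pattern(a), dinucleotide_pattern(b), separation)


def _pattern_to_dinuc(pattern) -> str:
    if len(pattern.symbols) != 2 or pattern.gaps != (1,):
        raise ValueError("closure member is not a dinucleotide pattern")
    return "".join(pattern.symbols)


@functools.lru_cache(maxsize=None)
def closure_indices(symmetry: str) -> tuple[tuple[int, ...], ...]:
    """For each of the 256 reference pair codes, the codes of its closure.

    The closure of a dinucleotide pair under words over {R, C} consists of
    dinucleotide pairs at the same separation, so it maps back into the 256
    reference codes; this is asserted here once.
    """
    S = SYMMETRIES[symmetry]
    out = []
    for a in DINUCLEOTIDES:
        for b in DINUCLEOTIDES:
            members = closure(S, _dinuc_pair(a, b))
            idx = tuple(
                sorted(
                    pair_index(_pattern_to_dinuc(m.first), _pattern_to_dinuc(m.second))
                    for m in members
                )
            )
            out.append(idx)
    return tuple(out)


@functools.lru_cache(maxsize=None)
def _flat_closure_arrays(symmetry: str):
    """Flattened (ref, member, 1/|closure|) arrays for vectorized I_S."""
    refs, mems, weights = [], [], []
    for ref, members in enumerate(closure_indices(symmetry)):
        w = 1.0 / len(members)
        for m in members:
            refs.append(ref)
            mems.append(m)
            weights.append(w)
    return (np.asarray(refs), np.asarray(mems), np.asarray(weights))


@dataclass
class SymmetryIndexCurve:
    """I_S(ell) on a grid of scales, with the sigma(ell) used."""

    symmetry: str
    scales: tuple[int, ...]
    values: np.ndarray
    sigma: np.ndarray

    def at(self, ell: int) -> float:
        return float(self.values[self.scales.index(ell)])

    def present(self, ell: int, threshold: float = PRESENCE_THRESHOLD) -> bool:
        v = self.at(ell)
        return bool(np.isfinite(v) and 0.0 <= v <= threshold)


@dataclass
class ScaleEstimates:
    """Detected characteristic scales (base pairs); None when undetectable."""

    L_D: float | None
    L_S: float | None
    L_M: float | None
    threshold: float = PRESENCE_THRESHOLD
    reasons: dict = field(default_factory=dict)


def sigma_at_scale(table: CorrelationTable, ell: int) -> float:
    """Population standard deviation of z over all pairs at one scale.

    NaN-flagged z values are excluded (and counted in the log); at least two
    defined values are required.
    """
    z = table.z_values(ell)
    valid = np.isfinite(z)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("sigma at ell=%d: excluding %d undefined z values", ell, n_bad)
    if valid.sum() < 2:
        raise ValueError(f"fewer than 2 defined z values at ell={ell}")
    return float(np.std(z[valid]))


def symmetry_distance(Y_ref: PairObservable, S: SymmetryDef,
                      table: CorrelationTable, ell: int) -> float:
    """Mean squared z spread of the closure of Y_ref, normalized by sigma^2."""
    members = closure(S, Y_ref)
    z = table.z_values(ell)
    z_vals, missing = {}, []
    for m in members:
        idx = pair_index(_pattern_to_dinuc(m.first), _pattern_to_dinuc(m.second))
        if not np.isfinite(z[idx]):
            missing.append(str(m))
        z_vals[m] = z[idx]
    if missing:
        raise ValueError(f"undefined z at ell={ell} for closure members: {missing}")
    sigma = sigma_at_scale(table, ell)
    if sigma == 0.0:
        raise ValueError(f"sigma(ell={ell}) is zero; distance undefined")
    ref_idx = pair_index(_pattern_to_dinuc(Y_ref.first), _pattern_to_dinuc(Y_ref.second))
    z_ref = z[ref_idx]
    return float(np.mean([(zv - z_ref) ** 2 for zv in z_vals.values()]) / sigma**2)


def index_curve(table: CorrelationTable, S: SymmetryDef | str,
                scales: tuple[int, ...] | None = None) -> SymmetryIndexCurve:
    """I_S(ell) over the table's scales (Eq. above, |A| = 256, ordered pairs).

    Scales where sigma is zero, or where any closure member's z is
    undefined, yield NaN with a logged message.
    """
    name = S if isinstance(S, str) else S.name
    refs, mems, weights = _flat_closure_arrays(name)
    ells = tuple(scales) if scales is not None else tuple(table.scales)
    values = np.full(len(ells), np.nan)
    sigmas = np.full(len(ells), np.nan)
    for i, ell in enumerate(ells):
        z = table.z_values(ell)
        valid = np.isfinite(z)
        if valid.sum() < 2:
            logger.info("I_%s undefined at ell=%d: fewer than 2 z values", name, ell)
            continue
        sigma = float(np.std(z[valid]))
        sigmas[i] = sigma
        if sigma == 0.0:
            logger.info("I_%s undefined at ell=%d: sigma is zero", name, ell)
            continue
        if not valid.all():
            # drop reference pairs whose closure touches an undefined z
            bad_term = ~valid[mems] | ~valid[refs]
            bad_refs = np.unique(refs[bad_term])
            keep = ~np.isin(refs, bad_refs)
            n_kept_refs = 256 - bad_refs.size
            logger.info(
                "I_%s at ell=%d: excluding %d reference pairs with undefined z",
                name, ell, bad_refs.size,
            )
            if n_kept_refs == 0:
                continue
            terms = weights[keep] * (z[mems[keep]] - z[refs[keep]]) ** 2
            values[i] = terms.sum() / (sigma**2 * 2 * n_kept_refs)
        else:
            terms = weights * (z[mems] - z[refs]) ** 2
            values[i] = terms.sum() / (sigma**2 * 2 * 256)
    return SymmetryIndexCurve(name, ells, values, sigmas)


def all_index_curves(table: CorrelationTable) -> dict[str, SymmetryIndexCurve]:
    """Index curves for the four registered symmetries on a common grid."""
    return {name: index_curve(table, name) for name in SYMMETRIES}


def detect_scales(curves: dict[str, SymmetryIndexCurve],
                  threshold: float = PRESENCE_THRESHOLD) -> ScaleEstimates:
    """First-crossing estimates of L_D, L_S, L_M on the curve grid.

    L_D is the smallest scale at which S2 is present (I_S2 <= threshold),
    L_S the smallest at which S3 is present, and L_M the smallest scale at
    which S1 has ceased to be present while S4 still is.  Estimates carry
    the grid resolution (one dyadic step); absence is reported with a
    reason, not an error.
    """
    reasons = {}

    def first_present(name):
        curve = curves[name]
        for ell in curve.scales:
            if curve.present(ell, threshold):
                return ell
        return None

    L_D = first_present("S2")
    if L_D is None:
        reasons["L_D"] = "S2 never present on the grid"
    L_S = first_present("S3")
    if L_S is None:
        reasons["L_S"] = "S3 never present on the grid"

    L_M = None
    s1, s4 = curves["S1"], curves["S4"]
    for ell in s1.scales:
        if ell in s4.scales and not s1.present(ell, threshold) and s4.present(ell, threshold):
            L_M = ell
            break
    if L_M is None:
        reasons["L_M"] = "no scale with S1 absent while S4 present"
    return ScaleEstimates(L_D, L_S, L_M, threshold, reasons)


def heatmap_table(curves_by_label: dict[str, dict[str, SymmetryIndexCurve]]) -> pd.DataFrame:
    """Per-sequence normalized intensity table for heatmap rendering.

    With I_min the minimum finite index within a sequence, intensity is 1
    (full color) at I <= 1.05 I_min, 0 (white) at I >= 6.5 I_min, linearly
    interpolated between.  If I_min is 0 the band degenerates: intensity is
    1 exactly where I == 0 and 0 elsewhere (flagged in the log).
    """
    rows = []
    for label, curves in curves_by_label.items():
        finite = [v for c in curves.values() for v in c.values if np.isfinite(v)]
        if not finite:
            raise ValueError(f"no finite index values for {label!r}")
        i_min = min(finite)
        if i_min == 0.0:
            logger.info("heatmap for %s: I_min is zero, degenerate color band", label)
        for name, curve in curves.items():
            for ell, v in zip(curve.scales, curve.values):
                if not np.isfinite(v):
                    intensity = np.nan
                elif i_min == 0.0:
                    intensity = 1.0 if v == 0.0 else 0.0
                else:
                    intensity = float(
                        np.clip((6.5 * i_min - v) / (6.5 * i_min - 1.05 * i_min), 0.0, 1.0)
                    )
                rows.append(
                    {"seq_label": label, "symmetry": name, "ell": ell,
                     "I": v, "intensity": intensity}
                )
    return pd.DataFrame(rows)
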