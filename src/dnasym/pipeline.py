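"""End-to-end orchestration: simulate or load, scan, index, detect, report.

A run takes either a FASTA file or a domain-model configuration, computes
the cross-correlation table, the four symmetry-index curves, the detected
characteristic scales and the heatmap intensity table, and writes everything
(plus a manifest sufficient to re-run bit-identically) to an output
directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .correlation_scan import ScaleGrid, scan_all_pairs
from .domain_model import DomainModelConfig, generate_genome
from .sequence_io import Sequence, clean_sequence, read_fasta, write_fasta
from .symmetry_index import (
    PRESENCE_THRESHOLD,
    all_index_curves,
    detect_scales,
    heatmap_table,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Parameters of one analysis run; exactly one input source."""

    fasta: str | None = None
    simulate: DomainModelConfig | None = None
    record_policy: str = "per-record"
    exponents: tuple[int, ...] = tuple(range(25))
    convention: str = "formula"
    threshold: float = PRESENCE_THRESHOLD
    outdir: str = "dnasym-out"
    plots: bool = False

    def __post_init__(self):
        if (self.fasta is None) == (self.simulate is None):
            raise ValueError("provide exactly one of fasta / simulate")


def _load_sequences(config: RunConfig, outdir: Path) -> list[Sequence]:
    if config.fasta is not None:
        cleaned = []
        for raw in read_fasta(config.fasta, config.record_policy):
            seq, removed = clean_sequence(raw)
            logger.info("cleaned %s: %.4f%% removed", seq.label, 100 * removed)
            cleaned.append(seq)
        return cleaned
    genome, ground_truth = generate_genome(config.simulate)
    write_fasta(genome, outdir / "genome.fa")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(ground_truth, fh, indent=1)
    return [genome]


def _analyze_one(seq: Sequence, config: RunConfig, outdir: Path, manifest: dict):
    grid = ScaleGrid(config.exponents)
    table = scan_all_pairs(seq, grid, config.convention)
    curves = all_index_curves(table)
    estimates = detect_scales(curves, config.threshold)

    stem = (seq.label or "sequence").replace("/", "_")
    corr_path = outdir / f"{stem}.correlations.tsv"
    table.to_frame().to_csv(corr_path, sep="\t", index=False, float_format=_FLOAT_FMT)

    curve_path = outdir / f"{stem}.index_curves.tsv"
    frame = heatmap_table({seq.label: curves})[["symmetry", "ell", "I"]]
    frame.insert(0, "seq_label", seq.label)
    frame.to_csv(curve_path, sep="\t", index=False, float_format=_FLOAT_FMT)

    scales_path = outdir / f"{stem}.scales.json"
    with open(scales_path, "w") as fh:
        json.dump(
            {
                "L_D": estimates.L_D,
                "L_S": estimates.L_S,
                "L_M": estimates.L_M,
                "threshold": estimates.threshold,
                "reasons": estimates.reasons,
            },
            fh,
            indent=1,
        )

    outputs = [corr_path.name, curve_path.name, scales_path.name]
    if config.plots:
        plot_path = outdir / f"{stem}.index_curves.png"
        plot_index_curves(curves, plot_path, threshold=config.threshold)
        outputs.append(plot_path.name)
    manifest["sequences"].append(
        {
            "label": seq.label,
            "length": seq.N,
            "dropped_scales": {str(k): v for k, v in table.dropped.items()},
            "outputs": outputs,
        }
    )
    return curves


def run_analysis(config: RunConfig) -> dict:
    """Run the full pipeline; returns the manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "input": config.fasta or "domain-model",
        "simulate": dataclasses.asdict(config.simulate) if config.simulate else None,
        "convention": config.convention,
        "exponents": list(config.exponents),
        "threshold": config.threshold,
        "record_policy": config.record_policy,
        "sequences": [],
        "complete": False,
    }
    if manifest["simulate"]:
        manifest["simulate"]["matrices"] = [
            np.asarray(M).tolist() for M in manifest["simulate"]["matrices"]
        ]
    curves_by_label = {}
    try:
        for seq in _load_sequences(config, outdir):
            curves_by_label[seq.label] = _analyze_one(seq, config, outdir, manifest)
        heat = heatmap_table(curves_by_label)
        heat.to_csv(outdir / "heatmap.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        manifest["complete"] = True
    finally:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return manifest


def run_multi(fasta_paths: list[str], base_config: RunConfig | None = None,
              outdir: str = "dnasym-out") -> dict:
    """Analyze several FASTA files; aggregate one heatmap table across all.

    Per-input failures are logged and the run continues; the manifest lists
    failures explicitly.
    """
    if not fasta_paths:
        raise ValueError("empty input list")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "runs": [], "failures": {}}
    frames = []
    for path in fasta_paths:
        sub = Path(path).stem
        cfg = dataclasses.replace(
            base_config or RunConfig(fasta=path), fasta=path, simulate=None,
            outdir=str(out / sub),
        )
        try:
            manifest["runs"].append(run_analysis(cfg))
            frames.append((out / sub / "heatmap.tsv"))
        except Exception as exc:  # noqa: BLE001 - per-input isolation
            logger.error("run failed for %s: %s", path, exc)
            manifest["failures"][str(path)] = str(exc)
    if frames:
        import pandas as pd

        combined = pd.concat([pd.read_csv(f, sep="\t") for f in frames], ignore_index=True)
        combined.to_csv(out / "heatmap.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def plot_index_curves(curves, path, threshold: float = PRESENCE_THRESHOLD):
    """Line plot of the four I_S(ell) curves plus presence color bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"S1": "tab:blue", "S2": "tab:green", "S3": "tab:red", "S4": "black"}
    fig, (ax, axbar) = plt.subplots(
        2, 1, figsize=(7, 5), sharex=True, height_ratios=[4, 1]
    )
    for name, curve in curves.items():
        ax.plot(curve.scales, curve.values, marker="o", ms=3,
                color=colors.get(name), label=name)
    ax.axhline(threshold, color="gray", lw=0.8, ls="--")
    ax.set_xscale("log", base=2)
    ax.set_yscale("log")
    ax.set_ylabel(r"$I_S(\ell)$")
    ax.legend()
    for i, (name, curve) in enumerate(sorted(curves.items())):
        vals = np.asarray(curve.values)
        with np.errstate(invalid="ignore"):
            alpha = np.clip(1.0 - vals / threshold, 0.0, 1.0)
        alpha[~np.isfinite(vals)] = 0.0
        for x, a in zip(curve.scales, alpha):
            axbar.bar(x, 0.8, bottom=i, width=x * 0.6, color=colors.get(name),
                      alpha=float(a), align="center")
    axbar.set_yticks([i + 0.4 for i in range(len(curves))], sorted(curves))
    axbar.set_xlabel(r"scale $\ell$ (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
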