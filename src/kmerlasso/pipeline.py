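"""End-to-end orchestration: windows -> features -> groups -> model -> hits.

A run directory receives every stage's output plus a manifest recording
the configuration, seed and SHA-256 checksums of all files, so that
re-running with identical inputs and seed is verifiable byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from kmerlasso import __version__
from kmerlasso.feature_grouping import cluster_features
from kmerlasso.group_analysis import (
    build_group_pfm,
    call_significant,
    export_hit_windows,
    locate_hits,
    pfm_consensus,
    write_meme_motif,
)
from kmerlasso.kmer_features import count_features, enumerate_features, select_features
from kmerlasso.sequence_io import (
    extract_windows,
    read_labeled_fasta,
    read_peaks,
    write_sequences,
    write_windows_bed,
)
from kmerlasso.sgl_model import cross_validate, fit

logger = logging.getLogger(__name__)

MODE_PRESETS = {
    "chip": {"n_top": 5000, "G": 20},
    "dnase": {"n_top": 30000, "G": 200},
}


@dataclass
class RunConfig:
    """All tunables of a full run; mode presets fill n_top and G."""

    mode: str = "chip"
    k: int = 8
    max_run: int = 2
    n_top: int | None = None
    G: int | None = None
    width: int = 150
    flank_gap: int = 300
    fdr: float = 0.05
    min_examples: int = 25
    folds: int = 10
    seed: int = 1
    lambda1_grid: list[float] | None = None
    lambda2_grid: list[float] | None = None
    grid_points: int = 8
    alpha: float = 1.5
    beta: float = 1.0
    peak_dialect: str = "narrowPeak"

    def __post_init__(self) -> None:
        if self.mode not in MODE_PRESETS:
            raise ValueError(f"mode must be one of {sorted(MODE_PRESETS)}")
        preset = MODE_PRESETS[self.mode]
        if self.n_top is None:
            self.n_top = preset["n_top"]
        if self.G is None:
            self.G = preset["G"]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunResult:
    outdir: Path
    fit: object
    reports: list
    manifest: dict = field(default_factory=dict)


def run_all(config: RunConfig, outdir: str | Path,
            peaks: str | Path | None = None,
            genome: str | Path | None = None,
            labeled_fasta: str | Path | None = None) -> RunResult:
    """Execute the full pipeline into ``outdir``.

    Inputs are either a peak file plus genome FASTA, or a pre-extracted
    labeled FASTA. Any stage failure aborts with the stage name; files
    already written are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        if labeled_fasta is not None:
            seqs = read_labeled_fasta(labeled_fasta)
        else:
            if peaks is None or genome is None:
                missing = "genome" if peaks is not None else "peaks"
                raise FileNotFoundError(
                    f"missing required resource: {missing} (supply peaks+genome "
                    f"or a labeled FASTA)")
            stage = "windows"
            peak_list = read_peaks(peaks, dialect=config.peak_dialect)
            seqs = extract_windows(peak_list, genome, width=config.width,
                                   flank_gap=config.flank_gap)
            write_sequences(seqs, outdir / "windows.fa")
            write_windows_bed(seqs, outdir / "windows.bed")
        n_pos = sum(1 for s in seqs if s.label > 0)
        logger.info("stage %s: %d sequences (%d positive)", stage, len(seqs), n_pos)

        stage = "featurize"
        space = enumerate_features(config.k, config.max_run)
        M_full = count_features(seqs, space)
        _, M = select_features(M_full, n_top=config.n_top)
        logger.info("stage featurize: %d features counted, %d selected",
                    M_full.n_features, M.n_features)

        stage = "cluster"
        assignment = cluster_features(M, G=min(config.G, M.n_features))
        logger.info("stage cluster: %d groups", assignment.G)

        stage = "train"
        l1, l2, cv_table = cross_validate(
            M, assignment, config.lambda1_grid, config.lambda2_grid,
            folds=config.folds, seed=config.seed)
        model = fit(M, assignment, l1, l2)
        model.cv_table = cv_table
        logger.info("stage train: lambda1=%.4g lambda2=%.4g, %d nonzero groups",
                    l1, l2, len(model.nonzero_groups))
        save_model(model, outdir / "model.json")
        cv_table.to_csv(outdir / "cv_table.tsv", sep="\t", index=False)

        stage = "report"
        seq_by_id = {s.id: s for s in seqs}
        reports = []
        rows = []
        for g in range(1, assignment.G + 1):
            rep = call_significant(model, M, g, fdr=config.fdr,
                                   min_examples=config.min_examples)
            reports.append(rep)
            rows.append({
                "group": g, "class": rep.class_label if rep.class_label else 0,
                "class_score_pos": rep.class_score_pos,
                "class_score_neg": rep.class_score_neg,
                "n_significant": rep.n_significant,
                "eligible_for_motif": rep.eligible_for_motif,
            })
        import pandas as pd

        pd.DataFrame(rows).to_csv(outdir / "group_report.tsv", sep="\t", index=False)

        stage = "hits"
        all_hits = []
        for rep in reports:
            if not rep.eligible_for_motif:
                continue
            hits = locate_hits(model, M, rep.group_id, seq_by_id, rep)
            all_hits.extend(hits)
            if len(hits) >= config.min_examples:
                pfm = build_group_pfm(hits, seq_by_id, config.k,
                                      min_examples=config.min_examples)
                write_meme_motif(pfm, f"group{rep.group_id}_{pfm_consensus(pfm)}",
                                 outdir / f"group{rep.group_id}_motif.meme")
        export_hit_windows(all_hits, seq_by_id,
                           outdir / "hits.fa", outdir / "hits.bed")
        logger.info("stage hits: %d hit windows exported", len(all_hits))

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": config.to_dict(),
            "n_sequences": len(seqs),
            "n_positive": n_pos,
            "nonzero_groups": model.nonzero_groups,
            "checksums": {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                          if p.is_file() and p.name != "manifest.json"},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return RunResult(outdir=outdir, fit=model, reports=reports, manifest=manifest)
    except Exception:
        logger.error("pipeline failed at stage %r (partial outputs kept in %s)",
                     stage, outdir)
        raise


def save_model(model, path: str | Path) -> None:
    """Serialize an SGLFit to JSON."""
    data = {
        "features": model.feature_names,
        "group_of": model.assignment.group_of.tolist(),
        "G": model.assignment.G,
        "w": model.w.tolist(),
        "lambda1": model.lambda1,
        "lambda2": model.lambda2,
        "intercept": model.intercept,
        "group_weight_exponent": model.group_weight_exponent,
        "converged": bool(model.converged),
        "n_iter": int(model.n_iter),
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def load_model(path: str | Path):
    from kmerlasso.feature_grouping import GroupAssignment
    from kmerlasso.sgl_model import SGLFit

    with open(path) as fh:
        data = json.load(fh)
    return SGLFit(
        w=np.asarray(data["w"]),
        lambda1=data["lambda1"], lambda2=data["lambda2"],
        assignment=GroupAssignment(group_of=np.asarray(data["group_of"]),
                                   G=data["G"]),
        objective_trace=np.empty(0),
        converged=data["converged"], n_iter=data["n_iter"],
        intercept=data.get("intercept", 0.0),
        group_weight_exponent=data.get("group_weight_exponent", 1.0),
        feature_names=data["features"])
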