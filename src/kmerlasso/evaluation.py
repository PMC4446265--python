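"""auROC evaluation and overlap-based validation against external peak sets.

auROC is computed from midranks, i.e. P(score_pos > score_neg) plus half
the tie probability, which is the Mann-Whitney U statistic normalized by
the number of positive-negative pairs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from kmerlasso.sequence_io import GenomicInterval, Peak, read_peaks

logger = logging.getLogger(__name__)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via midranks; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels > 0
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("auROC requires both classes")
    r = rankdata(scores)  # midranks
    u = r[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def train_test_split(peaks: list[Peak], n: int = 2000,
                     seed: int = 0) -> tuple[list[Peak], list[Peak]]:
    """Top-n peaks by score, split evenly into disjoint train/test halves.

    Fewer than n peaks triggers a warning and uses all of them. The
    split is a seeded random even partition; the same seed reproduces
    the same split.
    """
    ranked = sorted(peaks, key=lambda p: (-(p.score if p.score is not None else 0.0),
                                          p.interval.chrom, p.interval.start))
    if len(ranked) < n:
        logger.warning("only %d peaks available (requested %d); using all", len(ranked), n)
    top = ranked[: min(n, len(ranked))]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(top))
    half = len(top) // 2
    train = [top[i] for i in sorted(perm[:half])]
    test = [top[i] for i in sorted(perm[half:])]
    return train, test


def _overlap_len(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlap_labels(windows: list[GenomicInterval],
                   external: list[Peak],
                   min_overlap_fraction: float = 0.0) -> np.ndarray:
    """+1/-1 labels: does each window overlap any external peak?

    Overlap requires at least one shared base, or at least
    ``min_overlap_fraction`` of the window's length when that is set.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in external:
        by_chrom.setdefault(p.interval.chrom, []).append(p.interval)
    labels = np.full(len(windows), -1, dtype=np.int64)
    for i, w in enumerate(windows):
        need = max(1, int(np.ceil(min_overlap_fraction * len(w))))
        for iv in by_chrom.get(w.chrom, []):
            if _overlap_len(w, iv) >= need:
                labels[i] = 1
                break
    return labels


def validate_group(activations: np.ndarray,
                   windows: list[GenomicInterval],
                   external_peak_files: dict[str, str | Path],
                   dialect: str = "narrowPeak",
                   min_overlap_fraction: float = 0.0) -> list[tuple[str, float]]:
    """Rank external TF peak sets by how well a group's activations predict them.

    Each training window is labeled positive when it overlaps the
    external TF's peaks; the group's activations are scored against
    those labels by auROC. Returns (TF name, auROC) sorted descending;
    TFs with zero overlapping windows are skipped with a warning.
    """
    results: list[tuple[str, float]] = []
    for tf, path in external_peak_files.items():
        peaks = read_peaks(path, dialect=dialect)
        labels = overlap_labels(windows, peaks, min_overlap_fraction)
        if not (labels > 0).any():
            logger.warning("TF %s: no overlapping windows; skipped", tf)
            continue
        if (labels > 0).all():
            logger.warning("TF %s: every window overlaps; skipped", tf)
            continue
        results.append((tf, auroc(activations, labels)))
    results.sort(key=lambda t: -t[1])
    return results


def tf_in_top(results: list[tuple[str, float]], tf_names: set[str], top: int = 5) -> bool:
    """Is any of the named TFs (e.g. a family) among the top auROC hits?"""
    return any(name in tf_names for name, _ in results[:top])
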