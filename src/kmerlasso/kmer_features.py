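"""Wildcard k-mer feature space, counting, and discriminative selection.

Features are length-k words over {A,C,G,T} optionally carrying exactly one
contiguous interior run of wildcard positions ('.', matching any non-N
base). A pattern and its reverse complement are a single feature whose
canonical name is the lexicographically smaller of the pair; a count for
example i is the number of window positions at which the pattern or its
reverse complement matches the forward strand (palindromes and patterns
whose reverse complement also matches at the same position are counted
once per position). Windows containing N contribute nothing: N matches no
pattern position, wildcard or not.

Counting is vectorized: every window of the sequence is integer-encoded,
and per wildcard placement a precomputed lookup table maps the code of
the non-wildcard letters directly to the canonical feature index.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from kmerlasso.sequence_io import LabeledSequence

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN.", "TGCAN.")
_BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string or wildcard pattern."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(pattern: str) -> str:
    """Lexicographically smaller of a pattern and its reverse complement."""
    rc = revcomp(pattern)
    return pattern if pattern <= rc else rc


@dataclass(frozen=True)
class KmerPattern:
    """A canonical wildcard k-mer pattern."""

    pattern: str
    is_palindromic: bool

    def __str__(self) -> str:
        return self.pattern


# One entry per wildcard placement: (kept offsets within the window,
# lookup table mapping the base-4 code of the kept letters to the
# canonical feature index of the full enumeration).
_Variant = tuple[tuple[int, ...], np.ndarray]
_ENUM_CACHE: dict[tuple[int, int], tuple[list[KmerPattern], list[_Variant], dict[str, int]]] = {}


def _placements(k: int, max_run: int) -> list[tuple[int, int]]:
    """Wildcard run placements as (run_start, run_len); (0, 0) = exact."""
    out: list[tuple[int, int]] = [(0, 0)]
    for run_len in range(1, max_run + 1):
        for start in range(1, k - run_len):
            out.append((start, run_len))
    return out


def _full_enumeration(k: int, max_run: int):
    """Enumerate canonical patterns and build per-placement index tables."""
    key = (k, max_run)
    if key in _ENUM_CACHE:
        return _ENUM_CACHE[key]
    patterns: list[KmerPattern] = []
    index: dict[str, int] = {}
    variants: list[_Variant] = []
    for start, run_len in _placements(k, max_run):
        kept = tuple(j for j in range(k) if not (start <= j < start + run_len))
        n_letters = len(kept)
        table = np.empty(4 ** n_letters, dtype=np.int32)
        template = ["."] * k
        for code, letters in enumerate(itertools.product(_BASES, repeat=n_letters)):
            for j, base in zip(kept, letters):
                template[j] = base
            pat = "".join(template)
            can = canonical(pat)
            idx = index.get(can)
            if idx is None:
                idx = len(patterns)
                index[can] = idx
                patterns.append(KmerPattern(can, is_palindromic=can == revcomp(can)))
            table[code] = idx
        variants.append((kept, table))
    _ENUM_CACHE[key] = (patterns, variants, index)
    return _ENUM_CACHE[key]


@dataclass
class FeatureSpace:
    """Ordered collection of canonical wildcard k-mer patterns.

    A full space comes from :func:`enumerate_features`; subsets (from
    :func:`select_features`) keep the same ``k``/``max_run`` and reuse the
    full enumeration's lookup tables for counting.
    """

    k: int
    max_run: int
    patterns: list[KmerPattern]

    _index: dict[str, int] | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.patterns)

    @property
    def pattern_strings(self) -> list[str]:
        return [p.pattern for p in self.patterns]

    def index_of(self, pattern: str) -> int:
        if self._index is None:
            self._index = {p.pattern: i for i, p in enumerate(self.patterns)}
        return self._index[pattern]

    def __contains__(self, pattern: str) -> bool:
        if self._index is None:
            self._index = {p.pattern: i for i, p in enumerate(self.patterns)}
        return pattern in self._index

    def subset(self, indices: Sequence[int]) -> "FeatureSpace":
        return FeatureSpace(self.k, self.max_run, [self.patterns[i] for i in indices])


def enumerate_features(k: int = 8, max_run: int = 2) -> FeatureSpace:
    """Build the full canonical feature space for word length k.

    Contains every exact k-mer plus every pattern with one interior
    wildcard run of length 1..max_run, collapsed over reverse
    complement. Order is deterministic: placements by run length then
    run position, letters lexicographic, first appearance wins.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if not (0 <= max_run <= k - 2):
        raise ValueError(f"max_run must be in [0, k-2]; got {max_run} for k={k}")
    patterns, _, _ = _full_enumeration(k, max_run)
    return FeatureSpace(k=k, max_run=max_run, patterns=list(patterns))


@dataclass
class FeatureMatrix:
    """Per-example k-mer count vectors with labels.

    ``counts`` is examples x features (sparse CSR); column order matches
    ``space.patterns``.
    """

    example_ids: list[str]
    labels: np.ndarray
    counts: sp.csr_matrix
    space: FeatureSpace
    tasks: list[str] | None = None

    def __post_init__(self) -> None:
        n, p = self.counts.shape
        if len(self.example_ids) != n or len(self.labels) != n:
            raise ValueError("example ids/labels do not align with count rows")
        if p != len(self.space):
            raise ValueError("count columns do not align with the feature space")
        if self.tasks is not None and len(self.tasks) != n:
            raise ValueError("tasks do not align with count rows")

    @property
    def n_examples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def subset_features(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            example_ids=list(self.example_ids),
            labels=self.labels.copy(),
            counts=sp.csr_matrix(self.counts[:, idx]),
            space=self.space.subset(idx),
            tasks=list(self.tasks) if self.tasks is not None else None,
        )

    def subset_examples(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            example_ids=[self.example_ids[i] for i in idx],
            labels=self.labels[idx],
            counts=sp.csr_matrix(self.counts[idx]),
            space=self.space,
            tasks=[self.tasks[i] for i in idx] if self.tasks is not None else None,
        )


_ENCODE_LUT = np.full(128, -1, dtype=np.int64)
for _c, _v in _CODE.items():
    _ENCODE_LUT[ord(_c)] = _v


def _encode(seq: str) -> np.ndarray:
    codes = _ENCODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("sequence contains characters outside ACGTN")
    return codes


def _sequence_feature_counts(codes: np.ndarray, k: int,
                             variants: list[_Variant]) -> tuple[np.ndarray, np.ndarray]:
    """Canonical full-space feature indices and counts for one sequence."""
    L = len(codes)
    n_pos = L - k + 1
    if n_pos <= 0:
        raise ValueError(f"sequence length {L} shorter than k={k}")
    has_n = codes == 4
    # windows containing any N match nothing
    valid = ~(np.convolve(has_n, np.ones(k, dtype=int), mode="valid") > 0)
    if not valid.any():
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    pos = np.nonzero(valid)[0]
    safe_codes = np.where(has_n, 0, codes)  # masked positions are never used
    per_pos: list[np.ndarray] = []
    for kept, table in variants:
        word = np.zeros(len(pos), dtype=np.int64)
        for j in kept:
            word = word * 4 + safe_codes[pos + j]
        per_pos.append(table[word].astype(np.int64))
    idx = np.stack(per_pos)  # (n_variants, n_valid_pos)
    # de-duplicate within each position: a pattern (or its RC, or two
    # placements collapsing to the same canonical) counts once per position
    keys = np.unique(idx * len(pos) + np.arange(len(pos))[None, :])
    feats = keys // len(pos)
    uniq, cnt = np.unique(feats, return_counts=True)
    return uniq, cnt


def count_features(seqs: Sequence[LabeledSequence], space: FeatureSpace) -> FeatureMatrix:
    """Count canonical wildcard k-mer occurrences per labeled sequence."""
    full_patterns, variants, full_index = _full_enumeration(space.k, space.max_run)
    # map full-enumeration indices onto this space's columns
    col_of = np.full(len(full_patterns), -1, dtype=np.int64)
    for col, pat in enumerate(space.patterns):
        col_of[full_index[pat.pattern]] = col
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for i, s in enumerate(seqs):
        if len(s.seq) < space.k:
            raise ValueError(f"sequence {s.id!r} shorter than k={space.k}")
        uniq, cnt = _sequence_feature_counts(_encode(s.seq), space.k, variants)
        mapped = col_of[uniq]
        keep = mapped >= 0
        rows.append(np.full(keep.sum(), i, dtype=np.int64))
        cols.append(mapped[keep])
        vals.append(cnt[keep])
    n, p = len(seqs), len(space)
    counts = sp.csr_matrix(
        (np.concatenate(vals) if vals else [],
         (np.concatenate(rows) if rows else [], np.concatenate(cols) if cols else [])),
        shape=(n, p), dtype=np.float64)
    return FeatureMatrix(
        example_ids=[s.id for s in seqs],
        labels=np.array([s.label for s in seqs], dtype=np.int64),
        counts=counts,
        space=space,
        tasks=[s.task for s in seqs] if any(s.task is not None for s in seqs) else None,
    )


def standardize_columns(M: FeatureMatrix) -> FeatureMatrix:
    """Optional per-column unit-variance scaling (off by default everywhere).

    Counts are used raw in the model to match the objective over count
    vectors; this helper exists for experiments that want scale-free
    columns. Constant columns are left untouched.
    """
    X = np.asarray(M.counts.todense(), dtype=np.float64)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return FeatureMatrix(example_ids=list(M.example_ids), labels=M.labels.copy(),
                         counts=sp.csr_matrix(X / sd), space=M.space,
                         tasks=list(M.tasks) if M.tasks is not None else None)


def discriminative_scores(M: FeatureMatrix, eps: float = 1e-8) -> np.ndarray:
    """Two-class separation score per feature.

    |mean(positives) - mean(negatives)| / (pooled standard deviation + eps).
    Features constant across all examples score exactly 0.
    """
    pos = M.labels > 0
    neg = ~pos
    n1, n2 = int(pos.sum()), int(neg.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present for feature selection")
    X = M.counts
    Xp, Xn = X[pos], X[neg]
    m1 = np.asarray(Xp.mean(axis=0)).ravel()
    m2 = np.asarray(Xn.mean(axis=0)).ravel()
    sq1 = np.asarray(Xp.multiply(Xp).mean(axis=0)).ravel()
    sq2 = np.asarray(Xn.multiply(Xn).mean(axis=0)).ravel()
    v1 = np.maximum(sq1 - m1 ** 2, 0.0) * (n1 / max(n1 - 1, 1))
    v2 = np.maximum(sq2 - m2 ** 2, 0.0) * (n2 / max(n2 - 1, 1))
    dof = max(n1 + n2 - 2, 1)
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / dof)
    return np.abs(m1 - m2) / (pooled + eps)


def select_features(M: FeatureMatrix, n_top: int = 5000) -> tuple[FeatureSpace, FeatureMatrix]:
    """Keep the ``n_top`` most discriminative features.

    Ranking is by descending score with ties broken by pattern dictionary
    order; the reduced matrix's columns follow that ranking and example
    order is preserved.
    """
    if n_top <= 0:
        raise ValueError(f"n_top must be positive, got {n_top}")
    scores = discriminative_scores(M)
    names = M.space.pattern_strings
    order = sorted(range(len(names)), key=lambda i: (-scores[i], names[i]))
    keep = order[: min(n_top, len(order))]
    reduced = M.subset_features(keep)
    return reduced.space, reduced
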