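"""Per-group scoring, significance calling and hit localization.

Each surviving group of k-mers is associated with the peak (+1) or flank
(-1) class, examples significantly explained by the group are called
against an empirical null built from the opposite class, and for each
significant example the maximum-scoring k-mer position is located and a
50-base window around it exported for downstream motif summarization.

Two class-association conventions exist. The loss-form per-example score

    score(g, i) = log(1 + exp(-y_i w_g . x_{i,g}))

summed within each class associates the group with the class of the
larger sum ("loss_max" mode); because the loss decreases as the evidence
for an example's own class grows, the default mode instead compares mean
group activations w_g . x_{i,g} between classes, which orients groups by
where their k-mers actually occur. Null distributions and hit ranking
always use the activation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from kmerlasso.kmer_features import FeatureMatrix, revcomp
from kmerlasso.sequence_io import LabeledSequence
from kmerlasso.sgl_model import SGLFit

logger = logging.getLogger(__name__)


@dataclass
class GroupReport:
    """Class association and significance calls for one group."""

    group_id: int
    class_label: int | None  # +1, -1, or None for an all-zero group
    class_score_pos: float
    class_score_neg: float
    activations: np.ndarray  # per example, aligned with the matrix rows
    p_values: np.ndarray | None = None  # for examples of the group's class
    q_values: np.ndarray | None = None
    class_example_idx: np.ndarray | None = None  # row indices those p/q refer to
    n_significant: int = 0
    eligible_for_motif: bool = False

    @property
    def significant_idx(self) -> np.ndarray:
        """Row indices of significant examples (empty if none called)."""
        if self.q_values is None:
            return np.empty(0, dtype=int)
        return self.class_example_idx[self.q_values <= self._fdr]

    _fdr: float = 0.05


@dataclass
class HitCall:
    """Localized best k-mer match of a group within one example window."""

    example_id: str
    group_id: int
    position: int  # 0-based k-mer start within the window
    strand: str  # orientation of the matching pattern
    window_start: int  # 50-base window, clipped to the sequence
    window_end: int
    activation: float
    q_value: float


def class_scores(fit: SGLFit, M: FeatureMatrix, g: int,
                 mode: str = "activation") -> tuple[float, float, int | None]:
    """Class score sums and class association for group g.

    Returns (class_score_pos, class_score_neg, class) where the scores
    are the within-class sums of log(1 + exp(-y_i w_g.x_{i,g})). The
    class is chosen by mean-activation comparison ("activation", the
    default) or by the larger loss-form sum ("loss_max"). An all-zero
    group has class None.
    """
    if mode not in ("activation", "loss_max"):
        raise ValueError(f"unknown mode {mode!r}")
    idx = fit.assignment.members(g)
    if len(idx) == 0:
        raise KeyError(f"group {g} does not exist")
    wg = fit.w[idx]
    act = np.asarray(M.counts[:, idx] @ wg).ravel()
    y = M.labels.astype(np.float64)
    score = np.logaddexp(0.0, -y * act)
    pos, neg = M.labels > 0, M.labels < 0
    s_pos, s_neg = float(score[pos].sum()), float(score[neg].sum())
    if np.all(wg == 0.0):
        return s_pos, s_neg, None
    if mode == "loss_max":
        cls = 1 if s_pos >= s_neg else -1
    else:
        # the class the group's activations push examples toward: peak
        # groups have positive weights on peak-enriched k-mers (mean
        # activation > 0), flank groups negative weights on
        # flank-enriched k-mers (mean activation < 0)
        cls = 1 if act[pos].mean() + act[neg].mean() >= 0.0 else -1
    return s_pos, s_neg, cls


def empirical_pvalues(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Upper-tail empirical p-values with the +1 correction.

    p_i = (1 + #{null_j >= obs_i}) / (1 + N_null), never exactly zero.
    """
    if len(null) == 0:
        raise ValueError("empirical null is empty")
    null_sorted = np.sort(null)
    n_ge = len(null) - np.searchsorted(null_sorted, observed, side="left")
    return (1.0 + n_ge) / (1.0 + len(null))


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up q-values (monotone adjusted p-values)."""
    if len(p) == 0:
        return np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def call_significant(fit: SGLFit, M: FeatureMatrix, g: int,
                     fdr: float = 0.05, min_examples: int = 25,
                     mode: str = "activation") -> GroupReport:
    """Call examples significantly explained by group g.

    For a positive-class group the activations of the negative examples
    form the empirical null and p-values are assigned to the positive
    examples (mirrored for negative-class groups, where lower activation
    is stronger evidence). BH is applied within the group's class;
    significant means q <= fdr, and the group is motif-eligible when at
    least ``min_examples`` examples are significant.
    """
    s_pos, s_neg, cls = class_scores(fit, M, g, mode=mode)
    idx = fit.assignment.members(g)
    act = np.asarray(M.counts[:, idx] @ fit.w[idx]).ravel()
    report = GroupReport(group_id=g, class_label=cls,
                         class_score_pos=s_pos, class_score_neg=s_neg,
                         activations=act)
    report._fdr = fdr
    if cls is None:
        logger.info("group %d carries no weight; no significance calls", g)
        return report
    class_rows = np.nonzero(M.labels == cls)[0]
    null_rows = np.nonzero(M.labels == -cls)[0]
    if len(null_rows) == 0:
        raise ValueError("null class is empty")
    # for a negative-class group, smaller activation is stronger evidence
    sgn = 1.0 if cls == 1 else -1.0
    p = empirical_pvalues(sgn * act[class_rows], sgn * act[null_rows])
    q = benjamini_hochberg(p)
    report.p_values = p
    report.q_values = q
    report.class_example_idx = class_rows
    report.n_significant = int((q <= fdr).sum())
    report.eligible_for_motif = report.n_significant >= min_examples
    return report


# ---------------------------------------------------------------------------
# hit localization

def _group_patterns(fit: SGLFit, g: int) -> list[tuple[str, float]]:
    idx = fit.assignment.members(g)
    if fit.feature_names is None:
        raise ValueError("fit lacks feature names; cannot localize hits")
    return [(fit.feature_names[i], fit.w[i]) for i in idx if fit.w[i] != 0.0]


def _pattern_matches(pattern: str, seq: str) -> np.ndarray:
    """Boolean match vector of a wildcard pattern over all start positions."""
    k = len(pattern)
    L = len(seq)
    n_pos = L - k + 1
    if n_pos <= 0:
        return np.zeros(0, dtype=bool)
    out = np.ones(n_pos, dtype=bool)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n_code = ord("N")
    for j, c in enumerate(pattern):
        window = arr[j:j + n_pos]
        if c == ".":
            out &= window != n_code
        else:
            out &= window == ord(c)
    return out


def position_scores(fit: SGLFit, g: int, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-start-position group score and best orientation.

    Score at start p sums the weights of group patterns matching at p in
    either orientation (a pattern whose forward and reverse forms both
    match contributes once, like counting). Returns (scores, forward)
    where forward[p] says whether a forward-orientation match attains
    the score at p.
    """
    pats = _group_patterns(fit, g)
    n_pos = len(seq) - len(pats[0][0]) + 1 if pats else 0
    scores = np.zeros(max(n_pos, 0))
    fwd_any = np.zeros(max(n_pos, 0), dtype=bool)
    for pattern, weight in pats:
        m_f = _pattern_matches(pattern, seq)
        rc = revcomp(pattern)
        m_r = _pattern_matches(rc, seq) if rc != pattern else np.zeros_like(m_f)
        scores += weight * (m_f | m_r)
        fwd_any |= m_f
    return scores, fwd_any


def locate_hits(fit: SGLFit, M: FeatureMatrix, g: int,
                seqs: dict[str, LabeledSequence] | list[LabeledSequence],
                report: GroupReport, window: int = 50) -> list[HitCall]:
    """Locate the best-scoring k-mer position per significant example.

    The hit position is the argmax of the per-position group score
    (leftmost on ties; forward orientation preferred when both match),
    and the exported window spans ``window//2`` bases either side of the
    matched k-mer's center, clipped to the sequence.
    """
    if isinstance(seqs, list):
        seqs = {s.id: s for s in seqs}
    hits: list[HitCall] = []
    half = window // 2
    sig = report.significant_idx
    qmap = dict(zip(report.class_example_idx.tolist(),
                    report.q_values.tolist())) if report.q_values is not None else {}
    for row in sig:
        ex_id = M.example_ids[row]
        seq = seqs[ex_id].seq
        scores, fwd = position_scores(fit, g, seq)
        if scores.size == 0 or not np.any(scores != 0.0):
            logger.warning("example %s: no group pattern matches; skipped", ex_id)
            continue
        best = int(np.argmax(scores))  # argmax is leftmost on ties
        strand = "+" if fwd[best] else "-"
        kmer_len = len(fit.feature_names[fit.assignment.members(g)[0]])
        center = best + kmer_len // 2
        ws = max(0, center - half)
        we = min(len(seq), center + half)
        hits.append(HitCall(example_id=ex_id, group_id=g, position=best,
                            strand=strand, window_start=ws, window_end=we,
                            activation=float(report.activations[row]),
                            q_value=float(qmap.get(int(row), np.nan))))
    return hits


def export_hit_windows(hits: list[HitCall],
                       seqs: dict[str, LabeledSequence] | list[LabeledSequence],
                       fasta_path, bed_path=None) -> None:
    """Write hit windows as FASTA (and BED6 in genome coordinates).

    FASTA records are named example|group|position; windows clipped at a
    sequence edge carry an extra |len=N tag. BED rows are only written
    for hits whose examples carry genomic origins.
    """
    if isinstance(seqs, list):
        seqs = {s.id: s for s in seqs}
    with open(fasta_path, "w") as fh:
        for h in hits:
            sub = seqs[h.example_id].seq[h.window_start:h.window_end]
            name = f"{h.example_id}|group{h.group_id}|{h.position}"
            if h.window_end - h.window_start < 50:
                name += f"|len={h.window_end - h.window_start}"
            fh.write(f">{name}\n{sub}\n")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for h in hits:
                origin = seqs[h.example_id].origin
                if origin is None:
                    continue
                gs = origin.start + h.window_start
                ge = origin.start + h.window_end
                fh.write(f"{origin.chrom}\t{gs}\t{ge}\t"
                         f"{h.example_id}|group{h.group_id}\t0\t{h.strand}\n")


def build_group_pfm(hits: list[HitCall],
                    seqs: dict[str, LabeledSequence] | list[LabeledSequence],
                    k: int, min_examples: int = 25) -> np.ndarray:
    """Position frequency matrix (k x 4, columns A,C,G,T) over hit k-mers.

    Matched k-mers are aligned at their start; reverse-orientation
    matches are reverse complemented first. Each row sums to the number
    of usable hits.
    """
    if isinstance(seqs, list):
        seqs = {s.id: s for s in seqs}
    if len(hits) < min_examples:
        raise ValueError(f"need at least {min_examples} hits, got {len(hits)}")
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    pfm = np.zeros((k, 4))
    for h in hits:
        kmer = seqs[h.example_id].seq[h.position:h.position + k]
        if len(kmer) < k:
            continue
        if h.strand == "-":
            kmer = revcomp(kmer)
        for j, c in enumerate(kmer):
            if c in base_idx:
                pfm[j, base_idx[c]] += 1
    return pfm


def pfm_consensus(pfm: np.ndarray) -> str:
    return "".join("ACGT"[j] for j in pfm.argmax(axis=1))


def write_meme_motif(pfm: np.ndarray, name: str, path) -> None:
    """Write a PFM in MEME minimal motif format."""
    total = pfm.sum(axis=1, keepdims=True)
    ppm = np.where(total > 0, pfm / np.maximum(total, 1), 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\nBackground letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {pfm.shape[0]} "
                 f"nsites= {int(pfm.sum(axis=1).max())} E= 0\n")
        for row in ppm:
            fh.write(" " + "  ".join(f"{v:.6f}" for v in row) + "\n")
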