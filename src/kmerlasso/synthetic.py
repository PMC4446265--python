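"""Synthetic peak/flank sequence sets with planted motif instances.

The generator emulates the structure the model assumes: negatives are
pure background DNA from an order-1 Markov chain (by default with mild
CpG depletion, mimicking vertebrate genomic background), positives are
the same background carrying instances of one or more position
probability matrices (PPMs) in overlapping subsets of sequences, sampled
per column and inserted on either strand. A truth table records every
planted (motif id, start, strand) so recovery and localization can be
scored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from kmerlasso.kmer_features import revcomp
from kmerlasso.sequence_io import LabeledSequence

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass(eq=False)
class PlantSpec:
    """One motif to plant into the positive class.

    ``fraction`` of positives receive an instance, placed uniformly
    (avoiding ``edge_margin`` bases at either end so localization
    windows rarely clip) or with a center bias, reverse complemented
    with probability ``strand_prob``.
    """

    motif_id: str
    ppm: np.ndarray  # k_m x 4, rows sum to 1, columns A,C,G,T
    fraction: float = 1.0
    placement: str = "uniform"  # or "center"
    strand_prob: float = 0.5
    edge_margin: int = 5

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=np.float64)
        if self.ppm.ndim != 2 or self.ppm.shape[1] != 4:
            raise ValueError("PPM must be k x 4")
        if not np.allclose(self.ppm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PPM rows must sum to 1")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must be in [0, 1]")
        if self.placement not in ("uniform", "center"):
            raise ValueError(f"unknown placement {self.placement!r}")

    @property
    def length(self) -> int:
        return self.ppm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[j] for j in self.ppm.argmax(axis=1))


@dataclass
class SyntheticTruth:
    """Planted-instance records and generation parameters."""

    plants: dict[str, list[tuple[str, int, str]]]  # seq id -> (motif, start, strand)
    transition: np.ndarray
    stationary: np.ndarray
    seed: int
    skipped: int = 0  # instances dropped after repeated overlap redraws
    params: dict = field(default_factory=dict)

    def instances_of(self, motif_id: str) -> list[tuple[str, int, str]]:
        return [(sid, start, strand)
                for sid, items in self.plants.items()
                for mid, start, strand in items if mid == motif_id]


def default_transition(cpg_factor: float = 0.25) -> np.ndarray:
    """Order-1 background transitions with the C->G step downweighted."""
    T = np.full((4, 4), 0.25)
    T[1, 2] *= cpg_factor  # C followed by G
    T /= T.sum(axis=1, keepdims=True)
    return T


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _markov_sequence(rng: np.random.Generator, length: int,
                     T: np.ndarray, pi: np.ndarray) -> np.ndarray:
    from bisect import bisect_right

    cum_rows = [list(np.cumsum(row)) for row in T]
    cum_pi = list(np.cumsum(pi))
    u = rng.random(length).tolist()
    out = np.empty(length, dtype=np.int64)
    s = min(bisect_right(cum_pi, u[0]), 3)
    out[0] = s
    for i in range(1, length):
        s = min(bisect_right(cum_rows[s], u[i]), 3)
        out[i] = s
    return out


def _sample_instance(rng: np.random.Generator, ppm: np.ndarray) -> str:
    return "".join(_BASES[rng.choice(4, p=row)] for row in ppm)


def generate(n_pos: int, n_neg: int, width: int = 150,
             background: np.ndarray | str = "cpg_depleted",
             plants: list[PlantSpec] | None = None,
             seed: int = 0,
             task: str | None = None,
             id_prefix: str = "",
             exclusive: bool = False,
             neg_plants: list[PlantSpec] | None = None
             ) -> tuple[list[LabeledSequence], SyntheticTruth]:
    """Generate labeled positives/negatives with planted motif instances.

    Each positive independently receives each plant with its fraction;
    with ``exclusive=True`` the fractions instead partition the
    positives into disjoint subsets each carrying exactly one motif
    (one binding signal per peak), so fractions must sum to <= 1.
    Overlapping instances within a sequence are redrawn up to 100 times
    then skipped (counted in the truth record). ``neg_plants`` optionally
    plants motifs into the negative class as well (label-balanced decoy
    occurrences, mimicking motifs present genome-wide but not used in
    the assayed context); by default negatives are pure background.
    Fully reproducible from the seed.
    """
    plants = plants or []
    if isinstance(background, str):
        if background == "uniform":
            T = np.full((4, 4), 0.25)
        elif background == "cpg_depleted":
            T = default_transition()
        else:
            raise ValueError(f"unknown background {background!r}")
    else:
        T = np.asarray(background, dtype=np.float64)
        if T.shape != (4, 4) or not np.allclose(T.sum(axis=1), 1.0):
            raise ValueError("background transitions must be 4x4 rows summing to 1")
    for spec in plants:
        if spec.length > width:
            raise ValueError(f"motif {spec.motif_id} longer than window width")
    pi = stationary_distribution(T)
    rng = np.random.default_rng(seed)
    assigned: list[list[PlantSpec]] | None = None
    if exclusive:
        if sum(p.fraction for p in plants) > 1.0 + 1e-9:
            raise ValueError("exclusive planting needs fractions summing to <= 1")
        assigned = [[] for _ in range(n_pos)]
        order = rng.permutation(n_pos)
        at = 0
        for spec in plants:
            n_take = int(round(spec.fraction * n_pos))
            for j in order[at:at + n_take]:
                assigned[j].append(spec)
            at += n_take
    seqs: list[LabeledSequence] = []
    truth_plants: dict[str, list[tuple[str, int, str]]] = {}
    skipped = 0

    def plant_into(chars: list[str], specs: list[PlantSpec],
                   take: list[PlantSpec] | None) -> list[tuple[str, int, str]]:
        nonlocal skipped
        occupied: list[tuple[int, int]] = []
        placed: list[tuple[str, int, str]] = []
        for spec in specs:
            if take is not None:
                if spec not in take:
                    continue
            elif rng.random() >= spec.fraction:
                continue
            lo = spec.edge_margin
            hi = width - spec.length - spec.edge_margin
            if hi < lo:
                lo, hi = 0, width - spec.length
            start = None
            for _ in range(100):
                if spec.placement == "center":
                    mid = (lo + hi) / 2.0
                    cand = int(np.clip(round(rng.normal(mid, width / 8.0)), lo, hi))
                else:
                    cand = int(rng.integers(lo, hi + 1))
                if all(cand + spec.length <= s or cand >= e for s, e in occupied):
                    start = cand
                    break
            if start is None:
                skipped += 1
                continue
            inst = _sample_instance(rng, spec.ppm)
            strand = "-" if rng.random() < spec.strand_prob else "+"
            if strand == "-":
                inst = revcomp(inst)
            chars[start:start + spec.length] = list(inst)
            occupied.append((start, start + spec.length))
            placed.append((spec.motif_id, start, strand))
        return placed

    for i in range(n_pos):
        sid = f"{id_prefix}pos_{i}"
        codes = _markov_sequence(rng, width, T, pi)
        chars = list("".join(_BASES[c] for c in codes))
        placed = plant_into(chars, plants,
                            assigned[i] if assigned is not None else None)
        seqs.append(LabeledSequence(id=sid, seq="".join(chars), label=1, task=task))
        truth_plants[sid] = placed
    for i in range(n_neg):
        sid = f"{id_prefix}neg_{i}"
        codes = _markov_sequence(rng, width, T, pi)
        chars = list("".join(_BASES[c] for c in codes))
        placed = plant_into(chars, neg_plants or [], None)
        seqs.append(LabeledSequence(id=sid, seq="".join(chars), label=-1, task=task))
        truth_plants[sid] = placed
    truth = SyntheticTruth(
        plants=truth_plants, transition=T, stationary=pi, seed=seed,
        skipped=skipped,
        params={"n_pos": n_pos, "n_neg": n_neg, "width": width,
                "motifs": [p.motif_id for p in plants]})
    if skipped:
        logger.warning("%d plant instances skipped after 100 overlap redraws", skipped)
    return seqs, truth


def ppm_from_consensus(consensus: str, p_major: float = 0.85) -> np.ndarray:
    """Sharp PPM around a consensus word (off-consensus mass split evenly)."""
    k = len(consensus)
    ppm = np.full((k, 4), (1.0 - p_major) / 3.0)
    for i, c in enumerate(consensus):
        ppm[i, _BASES.index(c)] = p_major
    return ppm


def shuffled_negatives(positives: list[LabeledSequence],
                       seed: int = 0) -> list[LabeledSequence]:
    """Dinucleotide-shuffled copies of the positives as a negative set.

    An alternative to flanking windows: each negative preserves its
    positive's exact dinucleotide composition, making composition-only
    discrimination impossible.
    """
    out = []
    for i, s in enumerate(positives):
        out.append(LabeledSequence(id=f"shuf_{s.id}",
                                   seq=dinucleotide_shuffle(s.seq, seed=seed + i),
                                   label=-1, task=s.task))
    return out


def dinucleotide_shuffle(seq: str, seed: int = 0) -> str:
    """Shuffle preserving the exact dinucleotide multiset (Eulerian walk).

    The shuffled sequence starts and ends on the same bases as the input
    and has an identical dinucleotide count vector (Altschul-Erickson
    style: sample a uniform arborescence toward the last vertex, then
    walk the edge multigraph).
    """
    if len(seq) < 3:
        return seq
    rng = np.random.default_rng(seed)
    verts = sorted(set(seq))
    edges: dict[str, list[str]] = {v: [] for v in verts}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    # random arborescence rooted at the last character: random walk from
    # each vertex until hitting the root, keeping the exit edge (Wilson)
    tree_edge: dict[str, str] = {}
    for v in verts:
        if v == last:
            continue
        cur = v
        path: dict[str, str] = {}
        guard = 0
        while cur != last:
            nxt = str(rng.choice(edges[cur]))
            path[cur] = nxt
            cur = nxt
            guard += 1
            if guard > 10000:  # disconnected cannot happen for a real walk
                break
        for a, b in path.items():
            tree_edge[a] = b
    shuffled: dict[str, list[str]] = {}
    for v in verts:
        rest = list(edges[v])
        if v in tree_edge:
            rest.remove(tree_edge[v])
        rng.shuffle(rest)
        if v in tree_edge:
            rest.append(tree_edge[v])  # tree edge used last
        shuffled[v] = rest
    out = [seq[0]]
    ptr = {v: 0 for v in verts}
    cur = seq[0]
    total = len(seq) - 1
    for _ in range(total):
        nxt = shuffled[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)
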