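"""Genome/peak I/O and peak-vs-flank window extraction.

Coordinates are 0-based half-open throughout. Positive examples are
fixed-width windows centered on peak summits; negative examples are
equally sized windows centered a fixed distance upstream (lower
coordinate; peaks are treated as unstranded), which leaves a gap of
``flank_gap - width`` bases between the two windows at the defaults
(150 bp windows, 300 bp center-to-center offset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from pyfaidx import Fasta

logger = logging.getLogger(__name__)

VALID_STRANDS = frozenset({"+", "-", "."})


class PeakFileError(ValueError):
    """A peak file line that does not parse under the declared dialect."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called peak with a resolved summit coordinate.

    ``summit`` is absolute (genomic), not an offset; it must lie inside
    the interval.
    """

    interval: GenomicInterval
    summit: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.interval.start}, {self.interval.end})"
            )


@dataclass(frozen=True)
class LabeledSequence:
    """A fixed-width window with a class label (+1 peak / -1 flank)."""

    id: str
    seq: str
    label: int
    task: str | None = None
    origin: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.label not in (1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label}")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains invalid characters {sorted(bad)}")


def _midpoint_summit(start: int, end: int) -> int:
    return (start + end) // 2


def read_peaks(path: str | Path, dialect: str = "narrowPeak") -> list[Peak]:
    """Read a BED6 or ENCODE narrowPeak file into :class:`Peak` records.

    narrowPeak column 10 is the summit offset from ``start``; an offset
    of -1 (summit not called) falls back to the interval midpoint, as
    does the BED6 dialect, which carries no summit. Records are returned
    in file order; records whose summit falls outside the interval are
    dropped with a warning.
    """
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    peaks: list[Peak] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
                if dialect == "narrowPeak":
                    if len(fields) < 10:
                        raise IndexError("narrowPeak requires 10 columns")
                    offset = int(fields[9])
                    summit = start + offset if offset >= 0 else _midpoint_summit(start, end)
                else:
                    summit = _midpoint_summit(start, end)
                interval = GenomicInterval(chrom, start, end)
            except (IndexError, ValueError) as exc:
                raise PeakFileError(f"{path}: malformed line {lineno}: {exc}") from exc
            if not (start <= summit < end):
                n_rejected += 1
                logger.warning("%s line %d: summit %d outside interval, record rejected",
                               path, lineno, summit)
                continue
            peaks.append(Peak(interval=interval, summit=summit, score=score))
    if n_rejected:
        logger.warning("%s: %d records rejected (summit outside interval)", path, n_rejected)
    return peaks


@dataclass
class WindowStats:
    """Counts of window pairs dropped during extraction."""

    n_pairs: int = 0
    dropped_bounds: int = 0
    dropped_n: int = 0
    missing_chroms: list[str] = field(default_factory=list)


def _n_fraction(seq: str) -> float:
    return seq.count("N") / len(seq) if seq else 0.0


def extract_windows(
    peaks: Sequence[Peak],
    genome: str | Path | Fasta,
    width: int = 150,
    flank_gap: int = 300,
    max_n_fraction: float = 0.10,
    task: str | None = None,
    stats: WindowStats | None = None,
    exclude_flanks_in_peaks: bool = False,
) -> list[LabeledSequence]:
    """Extract labeled peak/flank window pairs from a genome.

    The positive window is ``[summit - width//2, summit + (width - width//2))``
    and the negative window is the same width centered ``flank_gap`` bases
    upstream of the summit. Pairs are dropped together when either window
    runs past a chromosome end or exceeds the N-fraction ceiling, so the
    two classes stay matched one-to-one. ``exclude_flanks_in_peaks``
    additionally drops pairs whose flank window overlaps any peak
    interval in the input (off by default: nearby peaks are kept).
    """
    fa = genome if isinstance(genome, Fasta) else Fasta(str(genome), sequence_always_upper=True)
    missing = sorted({p.interval.chrom for p in peaks} - set(fa.keys()))
    if missing:
        raise KeyError(f"chromosomes missing from genome: {', '.join(missing)}")
    st = stats if stats is not None else WindowStats()
    half = width // 2
    out: list[LabeledSequence] = []
    for idx, peak in enumerate(peaks):
        chrom = peak.interval.chrom
        chrom_len = len(fa[chrom])
        pos_start, pos_end = peak.summit - half, peak.summit - half + width
        neg_start, neg_end = pos_start - flank_gap, pos_end - flank_gap
        if neg_start < 0 or pos_end > chrom_len:
            st.dropped_bounds += 1
            logger.warning("peak %d (%s:%d): window out of bounds, pair dropped",
                           idx, chrom, peak.summit)
            continue
        if exclude_flanks_in_peaks:
            flank_iv = GenomicInterval(chrom, neg_start, neg_end)
            if any(flank_iv.overlaps(other.interval) for other in peaks):
                st.dropped_bounds += 1
                logger.warning("peak %d (%s:%d): flank overlaps a peak, pair dropped",
                               idx, chrom, peak.summit)
                continue
        pos_seq = str(fa[chrom][pos_start:pos_end]).upper()
        neg_seq = str(fa[chrom][neg_start:neg_end]).upper()
        if _n_fraction(pos_seq) > max_n_fraction or _n_fraction(neg_seq) > max_n_fraction:
            st.dropped_n += 1
            logger.warning("peak %d (%s:%d): N fraction above %.2f, pair dropped",
                           idx, chrom, peak.summit, max_n_fraction)
            continue
        st.n_pairs += 1
        out.append(LabeledSequence(
            id=f"peak_{idx}", seq=pos_seq, label=1, task=task,
            origin=GenomicInterval(chrom, pos_start, pos_end)))
        out.append(LabeledSequence(
            id=f"flank_{idx}", seq=neg_seq, label=-1, task=task,
            origin=GenomicInterval(chrom, neg_start, neg_end)))
    return out


def _header(s: LabeledSequence) -> str:
    parts = [s.id, f"label={'+1' if s.label > 0 else '-1'}"]
    if s.task is not None:
        parts.append(f"task={s.task}")
    if s.origin is not None:
        parts.append(f"origin={s.origin.chrom}:{s.origin.start}-{s.origin.end}")
    return "|".join(parts)


def write_sequences(seqs: Iterable[LabeledSequence], path: str | Path) -> None:
    """Write labeled sequences as FASTA with labels encoded in headers."""
    seqs = list(seqs)
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids: {dup}")
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{_header(s)}\n{s.seq}\n")


def read_labeled_fasta(path: str | Path) -> list[LabeledSequence]:
    """Read a labeled FASTA written by :func:`write_sequences`.

    Headers must carry a ``label=+1`` / ``label=-1`` tag; ``task=`` and
    ``origin=chrom:start-end`` tags are optional.
    """
    out: list[LabeledSequence] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        parts = header.split("|")
        seq_id = parts[0]
        tags = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
        if "label" not in tags:
            raise ValueError(f"header {header!r} missing label tag")
        label = int(tags["label"])
        origin = None
        if "origin" in tags:
            chrom, rng = tags["origin"].rsplit(":", 1)
            start, end = rng.split("-")
            origin = GenomicInterval(chrom, int(start), int(end))
        out.append(LabeledSequence(
            id=seq_id, seq="".join(chunks).upper(), label=label,
            task=tags.get("task"), origin=origin))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header, chunks = line[1:], []
            else:
                chunks.append(line)
        flush()
    return out


def write_windows_bed(seqs: Iterable[LabeledSequence], path: str | Path) -> None:
    """Emit window coordinates as BED6 (name carries the label)."""
    with open(path, "w") as fh:
        for s in seqs:
            if s.origin is None:
                continue
            fh.write(f"{s.origin.chrom}\t{s.origin.start}\t{s.origin.end}"
                     f"\t{s.id}\t{1 if s.label > 0 else 0}\t.\n")
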