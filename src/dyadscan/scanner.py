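"""Multi-scale sliding-window scan of contigs for inverted repeats.

Windows of several sizes (default 600/300/150 bp) step across each contig
by half their size, so every interior position is seen by at least two
windows per size track.  Each window contributes at most one candidate:
its optimal non-self-overlapping inverted repeat.  The scan is forward
strand only - an inverted repeat's reverse complement is itself an
inverted repeat, so a single-strand scan is complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

import pandas as pd

from .align import IRAlignment, pairing_string, self_ir_align
from .scoring import DEFAULT_SCHEME, ScoringScheme
from .sequence import NucleotideSequence

log = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZES = (600, 300, 150)


@dataclass(frozen=True)
class WindowScheme:
    """Window sizes with half-window skips.

    ``min_window`` drops truncated tail windows too short to hold an IR of
    the minimum reportable length.
    """

    sizes: Tuple[int, ...] = DEFAULT_WINDOW_SIZES
    min_window: int = 50

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.sizes)
        if not sizes:
            raise ValueError("need at least one window size")
        if any(a <= b for a, b in zip(sizes, sizes[1:])):
            raise ValueError("window sizes must be strictly decreasing")
        if any(s < 2 or s % 2 for s in sizes):
            raise ValueError("window sizes must be even and >= 2")
        object.__setattr__(self, "sizes", sizes)

    def skip(self, size: int) -> int:
        return size // 2


def enumerate_windows(length: int, scheme: WindowScheme) -> List[Tuple[int, int]]:
    """All (start, width) windows over a contig of *length* bp.

    Per size track: starts at multiples of the skip while start < length,
    the last windows truncated at the contig end; truncated windows
    shorter than ``scheme.min_window`` are dropped.
    """
    return [(start, width) for _, start, width in _enumerate_tracks(length, scheme)]


def _enumerate_tracks(length: int, scheme: WindowScheme) -> List[Tuple[int, int, int]]:
    """(track size, start, width) triples; width < track size only at the tail."""
    if length < 1:
        raise ValueError("contig length must be >= 1")
    out: List[Tuple[int, int, int]] = []
    for size in scheme.sizes:
        skip = scheme.skip(size)
        start = 0
        while start < length:
            width = min(size, length - start)
            if width >= max(scheme.min_window, 2):
                out.append((size, start, width))
            start += skip
    return out


@dataclass
class IRRecord:
    """A genome-anchored inverted-repeat candidate.

    Coordinates are 0-based half-open on the contig; ``start``/``end``
    cover both arms and the loop.  Metric fields stay None until
    :func:`dyadscan.filters.compute_metrics` runs.
    """

    contig: str
    start: int
    end: int
    arm1_start: int
    arm1_end: int
    arm2_start: int
    arm2_end: int
    window_size: int
    window_start: int
    score: int
    pairing: str
    sequence: str
    alignment: Optional[IRAlignment] = field(default=None, repr=False, compare=False)
    n: Optional[int] = None
    k: Optional[int] = None
    D: Optional[float] = None
    log10P: Optional[float] = None
    A: Optional[float] = None
    G: Optional[float] = None

    @property
    def span_length(self) -> int:
        return self.end - self.start

    def sort_key(self):
        return (self.contig, self.start, self.end, self.window_size, self.window_start)


#: columns of the tabular record representation, in file order
RECORD_COLUMNS = [
    "contig", "start", "end", "strand", "window_size", "window_start",
    "score", "k", "n", "D", "log10P", "A", "G", "span_length",
    "arm1_start", "arm1_end", "arm2_start", "arm2_end", "pairing", "sequence",
]


def record_from_alignment(
    contig: str,
    contig_seq: NucleotideSequence,
    window_start: int,
    window_size: int,
    aln: IRAlignment,
) -> IRRecord:
    """Translate a window-local alignment into genomic coordinates."""
    (a1s, a1e), (a2s, a2e) = aln.arms
    s, e = aln.span
    off = window_start
    return IRRecord(
        contig=contig,
        start=off + s,
        end=off + e,
        arm1_start=off + a1s,
        arm1_end=off + a1e,
        arm2_start=off + a2s,
        arm2_end=off + a2e,
        window_size=window_size,
        window_start=window_start,
        score=aln.score,
        pairing=pairing_string(aln),
        sequence=contig_seq.residues[off + s : off + e],
        alignment=aln,
    )


def scan(
    genome: Iterable[Tuple[str, NucleotideSequence]],
    scheme: WindowScheme = WindowScheme(),
    scoring: ScoringScheme = DEFAULT_SCHEME,
) -> List[IRRecord]:
    """Run the IR detector in every window of every contig.

    Returns at most one record per window; metrics are left uncomputed.
    A failure inside one window is logged and skipped, not fatal.
    """
    records: List[IRRecord] = []
    for contig, seq in genome:
        for track, start, width in _enumerate_tracks(len(seq), scheme):
            window = seq.subseq(start, start + width)
            try:
                aln = self_ir_align(window, scoring)
            except Exception:  # pragma: no cover - defensive isolation
                log.exception("window %s:%d(+%d) failed; skipping", contig, start, width)
                continue
            if aln is None:
                continue
            # records carry the nominal track size (not the truncated
            # width) so the dedup stage can group windows by track
            records.append(record_from_alignment(contig, seq, start, track, aln))
        log.info("scanned %s (%d bp): %d records so far", contig, len(seq), len(records))
    return records


def records_to_frame(records: Iterable[IRRecord]) -> pd.DataFrame:
    """Tabular view of records (strand always '+'; see design notes)."""
    rows = []
    for r in records:
        rows.append(
            {
                "contig": r.contig, "start": r.start, "end": r.end, "strand": "+",
                "window_size": r.window_size, "window_start": r.window_start,
                "score": r.score, "k": r.k, "n": r.n, "D": r.D,
                "log10P": r.log10P, "A": r.A, "G": r.G,
                "span_length": r.span_length,
                "arm1_start": r.arm1_start, "arm1_end": r.arm1_end,
                "arm2_start": r.arm2_start, "arm2_end": r.arm2_end,
                "pairing": r.pairing, "sequence": r.sequence,
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> List[IRRecord]:
    """Rebuild IRRecord objects (without live alignments) from a table."""
    required = set(RECORD_COLUMNS) - {"strand", "span_length"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"candidate table is missing columns: {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            IRRecord(
                contig=str(row.contig), start=int(row.start), end=int(row.end),
                arm1_start=int(row.arm1_start), arm1_end=int(row.arm1_end),
                arm2_start=int(row.arm2_start), arm2_end=int(row.arm2_end),
                window_size=int(row.window_size), window_start=int(row.window_start),
                score=int(row.score), pairing=str(row.pairing),
                sequence=str(row.sequence),
                n=None if pd.isna(row.n) else int(row.n),
                k=None if pd.isna(row.k) else int(row.k),
                D=None if pd.isna(row.D) else float(row.D),
                log10P=None if pd.isna(row.log10P) else float(row.log10P),
                A=None if pd.isna(row.A) else float(row.A),
                G=None if pd.isna(row.G) else float(row.G),
            )
        )
    return out
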