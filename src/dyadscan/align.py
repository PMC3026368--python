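"""Optimal inverted-repeat detection by local self-alignment.

A sequence is aligned against its own reverse complement with a
Smith-Waterman-style dynamic program (linear gap penalty).  Because query
and target are the same molecule, an optimum whose two arms map back to
overlapping positions of the original sequence cannot be read as a hairpin;
such cells are discarded and the best non-overlapping cell is taken
instead.  One alignment is reported per invocation.

Tie-breaking is deterministic: among equal-scoring end cells the smallest
(row, column) wins; within the recurrence, diagonal beats up beats left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from numba import njit

from .scoring import ScoringScheme, DEFAULT_SCHEME
from .sequence import NucleotideSequence, ALPHABET

# column classes
WC_MATCH = "WC_MATCH"
WOBBLE = "WOBBLE"
MISMATCH = "MISMATCH"
GAP = "GAP"

PAIRED_CLASSES = (WC_MATCH, WOBBLE)

GAP_CHAR = "-"

# complement in code space: A<->U, C<->G, N<->N
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)


@njit(cache=False)
def _fill_dp(q, t, sub, gap):
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    P = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up, 3 left
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            best = H[i - 1, j - 1] + sub[qi, t[j - 1]]
            ptr = 1
            up = H[i - 1, j] + gap
            if up > best:
                best = up
                ptr = 2
            left = H[i, j - 1] + gap
            if left > best:
                best = left
                ptr = 3
            if best <= 0:
                best = 0
                ptr = 0
            H[i, j] = best
            P[i, j] = ptr
    return H, P


@njit(cache=False)
def _trace_start(P, i, j):
    while P[i, j] != 0:
        p = P[i, j]
        if p == 1:
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    return i, j


@njit(cache=False)
def _pick_cell(H, P, L):
    """Best-scoring end cell whose traceback arms do not overlap on the
    original sequence.  Returns (i, j, i0, j0) or (-1, -1, -1, -1)."""
    n1, m1 = H.shape
    flat = H.ravel()
    # sort by score descending, then (row, col) ascending
    key = flat.astype(np.int64) * np.int64(flat.shape[0] + 1) - np.arange(
        flat.shape[0], dtype=np.int64
    )
    order = np.argsort(key)
    for idx in range(order.shape[0] - 1, -1, -1):
        cell = order[idx]
        score = flat[cell]
        if score <= 0:
            break
        i = cell // m1
        j = cell % m1
        i0, j0 = _trace_start(P, i, j)
        # query arm [i0, i); target arm on original coords [L - j, L - j0)
        lo = i0 if i0 > L - j else L - j
        hi = i if i < L - j0 else L - j0
        if lo >= hi:  # disjoint arms -> valid hairpin geometry
            return i, j, i0, j0
    return -1, -1, -1, -1


@dataclass
class Column:
    """One alignment column: residues (or '-') and a pairing class."""

    query: str
    target: str
    cls: str

    @property
    def is_pair(self) -> bool:
        return self.cls in PAIRED_CLASSES


@dataclass
class IRAlignment:
    """A local alignment of a sequence against its reverse complement.

    Spans are 0-based half-open: ``(q_start, q_end)`` on the input sequence,
    ``(t_start, t_end)`` on its reverse complement.  ``arm5`` / ``arm3`` are
    the two stem arms mapped back onto the input sequence, ``pairs`` the
    base-paired position pairs (a < b, local coordinates).
    """

    seq: NucleotideSequence
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    score: int
    columns: List[Column] = field(default_factory=list)

    @property
    def k(self) -> int:
        """Total alignment column count."""
        return len(self.columns)

    @property
    def n(self) -> int:
        """Paired column count (Watson-Crick plus wobble)."""
        return sum(1 for c in self.columns if c.is_pair)

    @property
    def arms(self) -> Tuple[Tuple[int, int], Tuple[int, int]]:
        L = len(self.seq)
        a = (self.q_start, self.q_end)
        b = (L - self.t_end, L - self.t_start)
        return (a, b) if a[0] <= b[0] else (b, a)

    @property
    def arm5(self) -> Tuple[int, int]:
        return self.arms[0]

    @property
    def arm3(self) -> Tuple[int, int]:
        return self.arms[1]

    @property
    def span(self) -> Tuple[int, int]:
        """Local interval covering both arms and the loop."""
        return self.arm5[0], self.arm3[1]

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s

    @property
    def pairs(self) -> List[Tuple[int, int]]:
        """Base-paired local position pairs, ordered by 5' position."""
        L = len(self.seq)
        out = []
        qpos = self.q_start
        tpos = self.t_start
        for col in self.columns:
            if col.query != GAP_CHAR and col.target != GAP_CHAR:
                if col.is_pair:
                    a, b = qpos, L - 1 - tpos
                    out.append((a, b) if a < b else (b, a))
                qpos += 1
                tpos += 1
            elif col.query != GAP_CHAR:
                qpos += 1
            else:
                tpos += 1
        out.sort()
        return out

    def rescore(self, scheme: ScoringScheme) -> int:
        """Independent re-sum of column scores; must equal ``score``."""
        total = 0
        for col in self.columns:
            if col.query == GAP_CHAR or col.target == GAP_CHAR:
                total += scheme.gap_penalty
            else:
                total += scheme.score(col.query, col.target)
        return total

    def run_lengths(self) -> List[int]:
        """Lengths of maximal runs of consecutive paired columns."""
        runs, cur = [], 0
        for col in self.columns:
            if col.is_pair:
                cur += 1
            elif cur:
                runs.append(cur)
                cur = 0
        if cur:
            runs.append(cur)
        return runs


def classify_columns(aln: IRAlignment, scheme: ScoringScheme = DEFAULT_SCHEME) -> IRAlignment:
    """(Re)label every column of *aln* in place and return it.

    Identical non-N letters are Watson-Crick pairs (identical letters in
    alignment space pair in hairpin space); query G vs target A and query U
    vs target C are wobble pairs; other residue columns are mismatches.
    """
    for col in aln.columns:
        if col.query == GAP_CHAR or col.target == GAP_CHAR:
            col.cls = GAP
        elif col.query == col.target and col.query != "N":
            col.cls = WC_MATCH
        elif scheme.is_wobble(col.query, col.target):
            col.cls = WOBBLE
        else:
            col.cls = MISMATCH
    return aln


def pairing_string(aln: IRAlignment) -> str:
    """Dot-bracket text over the alignment span (one char per nucleotide)."""
    if not aln.columns:
        raise ValueError("empty alignment has no pairing string")
    start, end = aln.span
    chars = ["."] * (end - start)
    for a, b in aln.pairs:
        chars[a - start] = "("
        chars[b - start] = ")"
    return "".join(chars)


def self_ir_align(
    seq: NucleotideSequence, scheme: ScoringScheme = DEFAULT_SCHEME
) -> Optional[IRAlignment]:
    """Optimal non-self-overlapping local alignment of *seq* vs its reverse
    complement, or ``None`` when no positive-scoring hairpin exists."""
    L = len(seq)
    if L < 2:
        raise ValueError("sequence too short to align (need length >= 2)")
    q = seq.codes()
    t = _COMP_CODE[q][::-1].copy()
    H, P = _fill_dp(q, t, scheme.substitution, np.int32(scheme.gap_penalty))
    i, j, i0, j0 = _pick_cell(H, P, L)
    if i < 0:
        return None
    score = int(H[i, j])

    # rebuild the column path from the pointer matrix
    rc = "".join(ALPHABET[c] for c in t)
    cols: List[Column] = []
    ci, cj = i, j
    while not (ci == i0 and cj == j0):
        p = P[ci, cj]
        if p == 1:
            cols.append(Column(seq.residues[ci - 1], rc[cj - 1], MISMATCH))
            ci -= 1
            cj -= 1
        elif p == 2:
            cols.append(Column(seq.residues[ci - 1], GAP_CHAR, GAP))
            ci -= 1
        else:
            cols.append(Column(GAP_CHAR, rc[cj - 1], GAP))
            cj -= 1
    cols.reverse()

    aln = IRAlignment(
        seq=seq, q_start=i0, q_end=i, t_start=j0, t_end=j, score=score, columns=cols
    )
    return classify_columns(aln, scheme)
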