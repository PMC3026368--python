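"""Validation against a known precursor set and parameter tuning.

A surviving candidate "identifies" a known precursor when the candidate's
sequence is a substring of the precursor or contains it (checked against
the precursor and its reverse complement, since the scan reports a single
strand).  The number of known entries identified - not the number of
matching records - is the IIR count.

The tuner replays cached scan metrics under different thresholds, so each
grid point costs a re-filter rather than a re-alignment, and searches for
the parameter set minimizing the candidate count subject to retaining at
least a target number of known precursors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import self_ir_align
from .dedup import remove_duplicates
from .filters import (
    FilterParams,
    apply_filters,
    avg_contig_A,
    density_D,
    gc_content_G,
    log10_probability,
)
from .scoring import DEFAULT_SCHEME, ScoringScheme
from .sequence import NucleotideSequence, read_fasta, revcomp_str


@dataclass(frozen=True)
class KnownSet:
    """Known precursor sequences used as the validation currency."""

    entries: Tuple[Tuple[str, NucleotideSequence], ...]

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in known set")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def from_fasta(cls, path) -> "KnownSet":
        return cls(tuple(read_fasta(path)))

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, NucleotideSequence]]) -> "KnownSet":
        return cls(tuple(pairs))


def match_known(records: Iterable, known: KnownSet) -> Tuple[int, Dict[str, int]]:
    """Count known entries identified by the surviving records.

    Returns (iir_count, map of entry id -> number of matching records).
    Invariant to record order and duplication.
    """
    seqs = [(eid, seq.residues, revcomp_str(seq.residues)) for eid, seq in known]
    hits: Dict[str, int] = {eid: 0 for eid, _ in known}
    rec_seqs = {r.sequence for r in records}
    for eid, fwd, rev in seqs:
        count = 0
        for rseq in rec_seqs:
            if (
                rseq in fwd
                or fwd in rseq
                or rseq in rev
                or rev in rseq
            ):
                count += 1
        hits[eid] = count
    iir = sum(1 for c in hits.values() if c > 0)
    return iir, hits


def metric_profile(
    known: KnownSet, scoring: ScoringScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Self-align every known entry and tabulate its D/P/A/G metrics.

    Entries whose self-alignment finds no inverted repeat appear with
    ``aligned = False`` and NaN metrics rather than being dropped.
    """
    rows = []
    for eid, seq in known:
        row = {
            "id": eid, "length": len(seq), "aligned": False,
            "n": np.nan, "k": np.nan, "D": np.nan, "log10P": np.nan,
            "A": np.nan, "G": np.nan, "span_length": np.nan,
        }
        aln = self_ir_align(seq, scoring) if len(seq) >= 2 else None
        if aln is not None:
            a = avg_contig_A(aln)
            g = gc_content_G(aln)
            row.update(
                aligned=True, n=aln.n, k=aln.k, D=density_D(aln),
                log10P=log10_probability(aln.n, aln.k),
                A=np.nan if a is None else a,
                G=np.nan if g is None else g,
                span_length=aln.span_length,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def profile_distributions(profile: pd.DataFrame) -> Dict[str, pd.Series]:
    """Frequency distributions with the conventional binning:
    D rounded to integer, P bucketed by decade exponent, A floored to one
    decimal, G floored to integer."""
    df = profile[profile["aligned"]]
    out = {}
    out["D"] = df["D"].round().astype(int).value_counts().sort_index()
    out["P_exponent"] = df["log10P"].apply(math.floor).astype(int).value_counts().sort_index()
    out["A"] = df["A"].dropna().apply(lambda a: math.floor(a * 10) / 10).value_counts().sort_index()
    out["G"] = df["G"].dropna().apply(math.floor).astype(int).value_counts().sort_index()
    return out


# ---------------------------------------------------------------------------
# parameter tuning


@dataclass
class TuningResult:
    params: FilterParams
    ir_count: int
    iir_count: int
    trace: List[Tuple[FilterParams, int, int]] = field(default_factory=list)


#: grid step per tunable threshold (P_max moves by decades)
DEFAULT_STEPS = {"D_min": 1.0, "A_min": 0.1, "G_min": 1.0, "P_max": 10.0}

_GRID_HALF_WIDTH = 5


def default_grid(
    start: FilterParams, free_params: Sequence[str], half_width: int = _GRID_HALF_WIDTH
) -> Dict[str, List[float]]:
    """Per-parameter value lists centered on the start point."""
    grid: Dict[str, List[float]] = {}
    for name in free_params:
        if name not in DEFAULT_STEPS:
            raise ValueError(f"unknown tunable parameter {name!r}")
        base = getattr(start, name)
        if name == "P_max":
            values = [base * 10.0 ** d for d in range(-half_width, half_width + 1)]
            values = [v for v in values if 0 < v <= 1]
        else:
            step = DEFAULT_STEPS[name]
            values = [round(base + d * step, 10) for d in range(-half_width, half_width + 1)]
            if name == "D_min":
                values = [v for v in values if 0 <= v < start.D_max]
            elif name == "A_min":
                values = [v for v in values if v >= 0]
            elif name == "G_min":
                values = [v for v in values if 0 <= v <= 100]
        grid[name] = values
    return grid


def _objective(ir: int, iir: int, target: int):
    """Total order on (ir, iir): feasible points first, fewest IRs wins;
    infeasible points chase the IIR target.  Lower tuples are better."""
    if iir >= target:
        return (0, ir, -iir)
    return (1, -iir, ir)


class _Evaluator:
    """Memoized (params -> ir_count, iir_count) on a cached scan."""

    def __init__(self, records, known: KnownSet, dedup: bool = True):
        self.records = list(records)
        self.known = known
        self.dedup = dedup
        self._cache: Dict[FilterParams, Tuple[int, int]] = {}

    def __call__(self, params: FilterParams) -> Tuple[int, int]:
        if params not in self._cache:
            kept, _ = apply_filters(self.records, params)
            if self.dedup:
                kept = remove_duplicates(kept)
            iir, _ = match_known(kept, self.known)
            self._cache[params] = (len(kept), iir)
        return self._cache[params]


def tune_parameters(
    records: Iterable,
    known: KnownSet,
    start: FilterParams,
    target_iir: int,
    free_params: Sequence[str] = ("A_min", "G_min"),
    grid: Optional[Dict[str, List[float]]] = None,
    mode: str = "grid",
    dedup: bool = True,
    max_iter: int = 200,
) -> TuningResult:
    """Search filter thresholds on a grid over *free_params*.

    ``mode="grid"`` evaluates every grid point (the trace then reproduces
    a full IR/IIR matrix when two parameters are free); ``mode="greedy"``
    walks to the best neighboring grid point until none improves or the
    iteration cap is hit.  The optimum is the evaluated point with the
    fewest candidates among those identifying >= *target_iir* known
    entries.
    """
    if target_iir > len(known):
        raise ValueError(f"target {target_iir} exceeds known-set size {len(known)}")
    evaluate = _Evaluator(records, known, dedup=dedup)
    free_params = list(free_params)
    if not free_params:
        ir, iir = evaluate(start)
        return TuningResult(start, ir, iir, [(start, ir, iir)])
    if grid is None:
        grid = default_grid(start, free_params)
    for name in free_params:
        if name not in grid or not grid[name]:
            raise ValueError(f"empty grid for {name!r}")

    trace: List[Tuple[FilterParams, int, int]] = []

    def probe(params: FilterParams) -> Tuple[int, int]:
        ir, iir = evaluate(params)
        trace.append((params, ir, iir))
        return ir, iir

    if mode == "grid":
        best = None
        for combo in itertools.product(*(grid[p] for p in free_params)):
            params = start.replace(**dict(zip(free_params, combo)))
            ir, iir = probe(params)
            key = _objective(ir, iir, target_iir)
            if best is None or key < best[0]:
                best = (key, params, ir, iir)
        _, params, ir, iir = best
        return TuningResult(params, ir, iir, trace)

    if mode == "greedy":
        # start from the grid point nearest the start parameters
        index = {
            p: min(range(len(grid[p])), key=lambda i: abs(grid[p][i] - getattr(start, p)))
            for p in free_params
        }
        current = start.replace(**{p: grid[p][index[p]] for p in free_params})
        cur_ir, cur_iir = probe(current)
        for _ in range(max_iter):
            best_move = None
            for p in free_params:
                for delta in (-1, 1):
                    i = index[p] + delta
                    if not 0 <= i < len(grid[p]):
                        continue
                    cand_index = dict(index, **{p: i})
                    cand = start.replace(**{q: grid[q][cand_index[q]] for q in free_params})
                    ir, iir = probe(cand)
                    key = _objective(ir, iir, target_iir)
                    if best_move is None or key < best_move[0]:
                        best_move = (key, cand_index, cand, ir, iir)
            if best_move is None or best_move[0] >= _objective(cur_ir, cur_iir, target_iir):
                break
            _, index, current, cur_ir, cur_iir = best_move
        return TuningResult(current, cur_ir, cur_iir, trace)

    raise ValueError(f"unknown mode {mode!r}")


def trace_matrix(
    result: TuningResult, row_param: str, col_param: str, what: str = "both"
) -> pd.DataFrame:
    """Pivot a two-parameter trace into a (row_param x col_param) matrix of
    'IRs' / 'IIRs' counts, one column pair per col_param value."""
    rows = []
    seen = set()
    for params, ir, iir in result.trace:
        key = (getattr(params, row_param), getattr(params, col_param))
        if key in seen:
            continue
        seen.add(key)
        rows.append({row_param: key[0], col_param: key[1], "IRs": ir, "IIRs": iir})
    df = pd.DataFrame(rows)
    value_cols = {"both": ["IRs", "IIRs"], "IRs": ["IRs"], "IIRs": ["IIRs"]}[what]
    return df.pivot(index=row_param, columns=col_param, values=value_cols).sort_index()
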