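"""The four hairpin-enrichment metrics and their threshold filters.

Metrics on an inverted-repeat alignment:

* ``D`` - pairing density: percent of alignment columns that are paired
  (Watson-Crick or wobble).  A "span" convention (paired bases over the
  genomic span) is also exposed.
* ``P`` - binomial point probability of observing exactly ``n`` paired
  positions among ``k`` with per-position success rate 1/4; carried in
  log10 space so values far below 1e-300 remain finite.
* ``A`` - mean length of maximal runs of consecutive paired columns.
* ``G`` - percent of G-C pairs among paired columns inside runs longer
  than 3 bp (shorter runs are more likely loop than stem).

A record passes when  L >= L_min,  D_min <= D <= D_max,  P <= P_max,
A >= A_min  and  G >= G_min;  all bounds are inclusive.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Sequence, Tuple

from scipy.special import gammaln

from .align import IRAlignment, WC_MATCH

_LN10 = math.log(10.0)

#: log-space slack so that P == P_max passes despite float rounding
_P_EPS = 1e-9


@dataclass(frozen=True)
class FilterParams:
    """Inclusive thresholds for the five filters (D has both bounds)."""

    D_min: float = 59.0
    D_max: float = 95.0
    P_max: float = 9.99e-9
    A_min: float = 2.2
    G_min: float = 18.0
    L_min: int = 50

    def __post_init__(self) -> None:
        if not (0 <= self.D_min < self.D_max <= 100):
            raise ValueError("need 0 <= D_min < D_max <= 100")
        if not (0 < self.P_max <= 1):
            raise ValueError("need 0 < P_max <= 1")
        if self.A_min < 0 or not (0 <= self.G_min <= 100) or self.L_min < 1:
            raise ValueError("invalid threshold")

    @property
    def log10_P_max(self) -> float:
        return math.log10(self.P_max)

    def replace(self, **kw) -> "FilterParams":
        return replace(self, **kw)

    @classmethod
    def base(cls) -> "FilterParams":
        """The base profile: D 59-95 %, P 9.99e-9, A 2.2 bp, G 18 %, L 50 bp."""
        return cls()

    @classmethod
    def optimal(cls) -> "FilterParams":
        """The tuned profile: D_min 60 %, P 9.99e-11, A 2.3 bp, G 24 %."""
        return cls(D_min=60.0, P_max=9.99e-11, A_min=2.3, G_min=24.0)


PROFILES = {"base": FilterParams.base, "optimal": FilterParams.optimal}


# ---------------------------------------------------------------------------
# metric primitives


def match_density(n: int, bases: int) -> float:
    """Percent of *bases* positions that are matches: 100 * n / bases."""
    if bases <= 0:
        raise ValueError("bases must be positive")
    if not 0 <= n <= bases:
        raise ValueError("need 0 <= n <= bases")
    return 100.0 * n / bases


def density_D(aln: IRAlignment, convention: str = "column") -> float:
    """Pairing density of an alignment, percent.

    ``column``: paired columns over total columns.  ``span``: paired bases
    (two per pair) over the genomic span length.
    """
    if convention == "column":
        return match_density(aln.n, aln.k)
    if convention == "span":
        return match_density(2 * aln.n, aln.span_length)
    raise ValueError(f"unknown convention {convention!r}")


def log10_probability(n: int, k: int) -> float:
    """log10 of  P(n, k) = 0.25^n * 0.75^(k-n) * C(k, n).

    Computed with log-gamma so exponents below -300 stay finite.
    """
    if k < 1 or not 0 <= n <= k:
        raise ValueError(f"need 0 <= n <= k, k >= 1; got n={n}, k={k}")
    ln_p = (
        n * math.log(0.25)
        + (k - n) * math.log(0.75)
        + float(gammaln(k + 1) - gammaln(n + 1) - gammaln(k - n + 1))
    )
    return ln_p / _LN10


def probability_P(n: int, k: int) -> float:
    """P(n, k) as a float (underflows to 0.0 below ~1e-308; prefer
    :func:`log10_probability` for comparisons)."""
    return 10.0 ** log10_probability(n, k)


def mantissa_exponent(log10_p: float) -> Tuple[float, int]:
    """Split a log10 probability into (mantissa in [1, 10), exponent)."""
    exp = math.floor(log10_p)
    return 10.0 ** (log10_p - exp), int(exp)


def mean_run_length(runs: Sequence[int]) -> float:
    """Arithmetic mean of contiguous paired-run lengths."""
    if not runs:
        raise ValueError("no paired runs")
    return sum(runs) / len(runs)


def avg_contig_A(aln: IRAlignment) -> Optional[float]:
    """Mean maximal paired-run length, or None when nothing pairs."""
    runs = aln.run_lengths()
    return mean_run_length(runs) if runs else None


def gc_content_G(aln: IRAlignment, min_run: int = 4) -> Optional[float]:
    """Percent of G-C/C-G pairs among paired columns in runs >= *min_run*.

    Wobble columns inside qualifying runs count in the denominator only.
    Returns None when no run reaches *min_run* (record is then rejected by
    the G filter rather than passed).
    """
    total = 0
    gc = 0
    run: List = []
    cols = list(aln.columns) + [None]  # sentinel flushes the last run
    for col in cols:
        if col is not None and col.is_pair:
            run.append(col)
            continue
        if len(run) >= min_run:
            total += len(run)
            gc += sum(1 for c in run if c.cls == WC_MATCH and c.query in "GC")
        run = []
    if total == 0:
        return None
    return 100.0 * gc / total


# ---------------------------------------------------------------------------
# record-level application


def compute_metrics(record) -> None:
    """Fill the D/P/A/G metric fields of an IRRecord from its alignment."""
    aln = record.alignment
    record.n = aln.n
    record.k = aln.k
    record.D = density_D(aln)
    record.log10P = log10_probability(aln.n, aln.k)
    record.A = avg_contig_A(aln)
    record.G = gc_content_G(aln)


def passes(record, params: FilterParams) -> bool:
    ok, _ = check_record(record, params)
    return ok


def check_record(record, params: FilterParams) -> Tuple[bool, List[str]]:
    """Evaluate one record; returns (passed, list of failed filter names)."""
    reasons = []
    if record.span_length < params.L_min:
        reasons.append("length")
    if record.D < params.D_min:
        reasons.append("density_low")
    if record.D > params.D_max:
        reasons.append("density_high")
    if record.log10P > params.log10_P_max + _P_EPS:
        reasons.append("probability")
    if record.A is None or record.A < params.A_min:
        reasons.append("stem_length")
    if record.G is None or record.G < params.G_min:
        reasons.append("gc_content")
    return not reasons, reasons


def apply_filters(
    records: Iterable, params: FilterParams
) -> Tuple[List, Counter]:
    """Split records into survivors and a per-filter rejection tally.

    A rejected record counts once in the tally of every filter it fails.
    """
    passing: List = []
    tally: Counter = Counter()
    for rec in records:
        ok, reasons = check_record(rec, params)
        if ok:
            passing.append(rec)
        else:
            tally.update(reasons)
    return passing, tally
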