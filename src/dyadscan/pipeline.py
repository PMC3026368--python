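"""End-to-end candidate pipeline: scan -> metrics -> filters -> dedup."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, List, Tuple

from .dedup import remove_duplicates
from .filters import FilterParams, apply_filters, compute_metrics
from .scanner import IRRecord, WindowScheme, scan
from .scoring import DEFAULT_SCHEME, ScoringScheme
from .sequence import NucleotideSequence


@dataclass
class PipelineResult:
    raw: List[IRRecord]         # every window hit, metrics computed
    filtered: List[IRRecord]    # after threshold filters
    deduped: List[IRRecord]     # after same-track duplicate removal
    tally: Counter = field(default_factory=Counter)

    @property
    def counts(self) -> dict:
        return {
            "scanned": len(self.raw),
            "filtered": len(self.filtered),
            "deduplicated": len(self.deduped),
        }


def run_pipeline(
    genome: Iterable[Tuple[str, NucleotideSequence]],
    params: FilterParams,
    window_scheme: WindowScheme = WindowScheme(),
    scoring: ScoringScheme = DEFAULT_SCHEME,
    dedup: bool = True,
) -> PipelineResult:
    """Scan the genome and push candidates through the full filter chain.

    Duplicate removal runs after the metric filters (the stage order is a
    contract, not an optimization).
    """
    raw = scan(genome, window_scheme, scoring)
    for rec in raw:
        compute_metrics(rec)
    filtered, tally = apply_filters(raw, params)
    deduped = remove_duplicates(filtered) if dedup else list(filtered)
    return PipelineResult(raw=raw, filtered=filtered, deduped=deduped, tally=tally)
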