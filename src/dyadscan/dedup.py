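"""Removal of duplicate candidates from adjacent same-size windows.

Half-window skips mean every inverted repeat can be found twice by the
same size track.  Within each (contig, window size) group, records whose
windows start exactly one skip apart and whose genomic spans overlap are
treated as duplicates and the shorter span is dropped (ties broken by
lower score, then later window start).  Records from different window
sizes are never compared.  This stage runs after the metric filters.

Known limitation, kept deliberately: two genuinely distinct but nearby
identical IRs caught by adjacent windows are collapsed too - span overlap
cannot tell them apart from scan duplicates.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, List

from .scanner import IRRecord


def _loses(a: IRRecord, b: IRRecord) -> bool:
    """True when *a* is the record to drop from an overlapping pair."""
    ka = (a.span_length, a.score, -a.window_start)
    kb = (b.span_length, b.score, -b.window_start)
    return ka < kb


def remove_duplicates(records: Iterable[IRRecord]) -> List[IRRecord]:
    """Drop same-track adjacent-window overlaps; order by (contig, start)."""
    records = list(records)
    groups = defaultdict(list)
    for idx, rec in enumerate(records):
        groups[(rec.contig, rec.window_size)].append(idx)

    dropped = set()
    for (_, size), idxs in groups.items():
        skip = size // 2
        idxs = sorted(idxs, key=lambda i: records[i].window_start)
        for pos, i in enumerate(idxs):
            a = records[i]
            for j in idxs[pos + 1 :]:
                b = records[j]
                if b.window_start - a.window_start > skip:
                    break
                if b.window_start - a.window_start != skip:
                    continue
                if a.start < b.end and b.start < a.end:  # spans overlap
                    dropped.add(i if _loses(a, b) else j)

    kept = [rec for idx, rec in enumerate(records) if idx not in dropped]
    kept.sort(key=IRRecord.sort_key)
    return kept
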