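"""Scoring scheme for aligning a sequence against its own reverse complement.

The default substitution matrix rewards identical letters (which, after
reverse complementation, are Watson-Crick pairs in hairpin space) and gives
a mild -2 penalty to the two column types that correspond to G.U wobble
pairs: query G vs target A, and query U vs target C.  The matrix is
intentionally asymmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence import ALPHABET, CODE

_DEFAULT = np.array(
    [
        # A   C   G   U   N
        [5, -4, -4, -4, 0],   # A
        [-4, 5, -4, -4, 0],   # C
        [-2, -4, 5, -4, 0],   # G   (G vs A column = G.U wobble)
        [-4, -2, -4, 5, 0],   # U   (U vs C column = U.G wobble)
        [0, 0, 0, 0, 3],      # N
    ],
    dtype=np.int32,
)

DEFAULT_GAP_PENALTY = -6


@dataclass(frozen=True)
class ScoringScheme:
    """5x5 substitution matrix over {A,C,G,U,N} plus a linear gap penalty.

    Rows index the query residue, columns the target (reverse-complement)
    residue.  The gap penalty applies per gap column.
    """

    substitution: np.ndarray = field(default_factory=lambda: _DEFAULT.copy())
    gap_penalty: int = DEFAULT_GAP_PENALTY

    def __post_init__(self) -> None:
        sub = np.asarray(self.substitution, dtype=np.int32)
        if sub.shape != (5, 5):
            raise ValueError("substitution matrix must be 5x5 over ACGUN")
        if self.gap_penalty >= 0:
            raise ValueError("gap penalty must be negative")
        object.__setattr__(self, "substitution", sub)

    def score(self, query: str, target: str) -> int:
        """Substitution score for one aligned column (no gaps)."""
        return int(self.substitution[CODE[query], CODE[target]])

    def is_wobble(self, query: str, target: str) -> bool:
        """Column types that read as G.U pairs after reverse complementation."""
        return (query, target) in (("G", "A"), ("U", "C"))


DEFAULT_SCHEME = ScoringScheme()

__all__ = ["ScoringScheme", "DEFAULT_SCHEME", "DEFAULT_GAP_PENALTY", "ALPHABET"]
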