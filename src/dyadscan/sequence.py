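"""Nucleotide sequences on the RNA alphabet {A, C, G, U, N}.

All genomic input is translated to RNA on ingest (T -> U); IUPAC ambiguity
codes other than N collapse to N.  Coordinates, when present, are 0-based
half-open on the source contig.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

import numpy as np

ALPHABET = "ACGUN"

#: residue -> small-int code used by the alignment kernels
CODE = {b: i for i, b in enumerate(ALPHABET)}

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

# IUPAC nucleotide one-letter codes; everything ambiguous except N maps to N
_IUPAC_TO_RNA = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "ACGUUNNNNNNNNNNNACGUUNNNNNNNNNNN",
)


class SequenceError(ValueError):
    """Raised for residues outside the IUPAC nucleotide alphabet."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An RNA-alphabet sequence, optionally anchored to a source contig."""

    residues: str
    contig: Optional[str] = None
    start: int = 0

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError("empty sequence")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise SequenceError(f"invalid residues {sorted(bad)!r}; expected {ALPHABET}")

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, item):
        return self.residues[item]

    @property
    def end(self) -> int:
        return self.start + len(self.residues)

    def codes(self) -> np.ndarray:
        """Residues as an int8 array (A=0, C=1, G=2, U=3, N=4)."""
        return np.frombuffer(
            self.residues.encode().translate(_CODE_BYTES), dtype=np.int8
        ).copy()

    def subseq(self, start: int, end: int) -> "NucleotideSequence":
        """Slice by local coordinates, keeping the genomic anchor consistent."""
        return NucleotideSequence(
            self.residues[start:end], contig=self.contig, start=self.start + start
        )


_CODE_BYTES = bytes.maketrans(b"ACGUN", bytes(range(5)))


def dna_to_rna(text: str, contig: Optional[str] = None, start: int = 0) -> NucleotideSequence:
    """Translate raw sequence text (DNA or RNA, any case) to the RNA alphabet.

    T/t becomes U, ambiguity codes other than N become N; characters outside
    the IUPAC nucleotide set raise :class:`SequenceError`.
    """
    if not text:
        raise SequenceError("empty sequence text")
    rna = text.translate(_IUPAC_TO_RNA)
    return NucleotideSequence(rna, contig=contig, start=start)


def reverse_complement(seq: NucleotideSequence) -> NucleotideSequence:
    """A<->U, C<->G, N<->N, order reversed; the genomic anchor is dropped."""
    return NucleotideSequence(seq.residues.translate(_COMPLEMENT)[::-1])


def revcomp_str(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> Iterator[tuple[str, NucleotideSequence]]:
    """Stream (contig id, RNA sequence) records from a FASTA file.

    Gzip-transparent.  Ids are truncated at the first whitespace.  Raises
    :class:`SequenceError` with a line number for text before the first
    header or for invalid residues.
    """
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        # Bio.SeqIO silently ignores junk before the first '>'; check ourselves.
        pos = fh.tell()
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise SequenceError(f"{path}:{lineno}: expected FASTA header, got {line.strip()[:30]!r}")
            break
        fh.seek(pos)
        for rec in SeqIO.parse(fh, "fasta"):
            try:
                yield rec.id, dna_to_rna(str(rec.seq), contig=rec.id, start=0)
            except SequenceError as exc:
                raise SequenceError(f"{path}: record {rec.id}: {exc}") from exc
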