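"""Synthetic genomes with planted hairpins and truth annotations.

Each hairpin is built as a random 5' arm, a loop, and the exact reverse
complement of the arm; the 3' arm is then degraded (wobble conversions,
substitutions, indels) to emulate duplication-then-divergence.  Plants are
written into i.i.d. background of configurable GC content at
non-overlapping loci.  Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .align import IRAlignment
from .sequence import NucleotideSequence, revcomp_str

_BASES = np.array(list("ACGU"))
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

#: clearance kept between plants and around contig edges
PLANT_MARGIN = 20


def _is_pair(a: str, b: str) -> bool:
    """Watson-Crick or G.U wobble."""
    return _COMPLEMENT.get(a) == b or {a, b} == {"G", "U"}


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of a synthetic genome with planted hairpins."""

    stem_length: int = 30
    loop_length: int = 8
    wobble_fraction: float = 0.0
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    count: int = 10
    background_length: int = 10_000
    background_gc: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("wobble_fraction", "substitution_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.stem_length < 1:
            raise ValueError("stem_length must be >= 1")
        if self.loop_length < 3:
            raise ValueError("loop_length must be >= 3 (hairpins need a loop)")
        if not 0 < self.background_gc < 1:
            raise ValueError("background_gc must be in (0, 1)")
        need = self.count * (2 * self.stem_length + self.loop_length + 2 * PLANT_MARGIN)
        if need > self.background_length:
            raise ValueError(
                f"cannot fit {self.count} hairpins into {self.background_length} bp"
            )


@dataclass
class Plant:
    """One planted hairpin and its realized degradation statistics."""

    id: str
    start: int
    end: int
    sequence: str  # RNA alphabet
    stem_length: int
    paired: int  # stem positions still pairing (WC or wobble), pre-indel
    n_subs: int
    n_indels: int
    n_wobbles: int

    @property
    def paired_fraction(self) -> float:
        return self.paired / self.stem_length


@dataclass
class GenomeFixture:
    contig: str
    sequence: str  # RNA alphabet
    plants: List[Plant]
    spec: PlantSpec

    def genome(self) -> List[Tuple[str, NucleotideSequence]]:
        """In-memory view suitable for :func:`dyadscan.scanner.scan`."""
        return [(self.contig, NucleotideSequence(self.sequence, contig=self.contig))]

    def to_fasta(self, width: int = 60) -> str:
        """FASTA text in the DNA alphabet (U written as T)."""
        dna = self.sequence.replace("U", "T")
        lines = [f">{self.contig}"]
        lines += [dna[i : i + width] for i in range(0, len(dna), width)]
        return "\n".join(lines) + "\n"

    def to_bed(self) -> str:
        """BED6 truth track; score = realized paired fraction x 1000."""
        lines = []
        for p in self.plants:
            score = int(round(p.paired_fraction * 1000))
            lines.append(f"{self.contig}\t{p.start}\t{p.end}\t{p.id}\t{score}\t+")
        return "\n".join(lines) + ("\n" if lines else "")


def expected_paired_fraction(substitution_rate: float) -> float:
    """Closed-form expected surviving pair fraction under substitution-only
    degradation (wobble and indel rates zero).

    A substituted 3'-arm base breaks its pair unless the replacement forms a
    wobble, which is possible for exactly one of the three alternatives and
    only when the 5' partner is G or U (probability 1/2 for GC-balanced
    arms): survival = 1 - r + r * (1/3) * (1/2) = 1 - (5/6) r.
    """
    return 1.0 - substitution_rate * 5.0 / 6.0


def _sample(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=n, p=p))


def _build_hairpin(rng: np.random.Generator, spec: PlantSpec):
    k = spec.stem_length
    arm5 = _sample(rng, k, spec.background_gc)
    loop = _sample(rng, spec.loop_length, spec.background_gc)
    arm3 = list(revcomp_str(arm5))

    n_wobbles = 0
    for j in range(k):
        partner = arm5[k - 1 - j]
        if partner == "G" and arm3[j] == "C" and rng.random() < spec.wobble_fraction:
            arm3[j] = "U"
            n_wobbles += 1

    n_subs = 0
    for j in range(k):
        if rng.random() < spec.substitution_rate:
            others = [b for b in "ACGU" if b != arm3[j]]
            arm3[j] = others[rng.integers(3)]
            n_subs += 1

    paired = sum(1 for j in range(k) if _is_pair(arm5[k - 1 - j], arm3[j]))

    n_indels = 0
    out: List[str] = []
    for b in arm3:
        if rng.random() < spec.indel_rate:
            n_indels += 1
            if rng.random() < 0.5:
                continue  # deletion
            out.append(b)
            out.append(str(rng.choice(_BASES)))  # insertion
        else:
            out.append(b)

    seq = arm5 + loop + "".join(out)
    return seq, paired, n_subs, n_indels, n_wobbles


def make_genome(spec: PlantSpec, contig: str = "sim1") -> GenomeFixture:
    """Generate the background, plant the hairpins, return the fixture."""
    rng = np.random.default_rng(spec.seed)
    background = list(_sample(rng, spec.background_length, spec.background_gc))

    placed: List[Tuple[int, int]] = []
    plants: List[Plant] = []
    for idx in range(spec.count):
        seq, paired, n_subs, n_indels, n_wobbles = _build_hairpin(rng, spec)
        lo = PLANT_MARGIN
        hi = spec.background_length - len(seq) - PLANT_MARGIN
        if hi <= lo:
            raise ValueError("hairpins cannot fit in the background")
        start = None
        for _ in range(1000):
            cand = int(rng.integers(lo, hi))
            if all(
                cand + len(seq) + PLANT_MARGIN <= s or e + PLANT_MARGIN <= cand
                for s, e in placed
            ):
                start = cand
                break
        if start is None:
            raise ValueError("could not place all hairpins without overlap")
        placed.append((start, start + len(seq)))
        background[start : start + len(seq)] = list(seq)
        plants.append(
            Plant(
                id=f"plant{idx:03d}", start=start, end=start + len(seq),
                sequence=seq, stem_length=spec.stem_length, paired=paired,
                n_subs=n_subs, n_indels=n_indels, n_wobbles=n_wobbles,
            )
        )
    plants.sort(key=lambda p: p.start)
    return GenomeFixture(contig=contig, sequence="".join(background), plants=plants, spec=spec)


# ---------------------------------------------------------------------------
# the hand-built worked example


def worked_example_fixture() -> IRAlignment:
    """A 63-nt hairpin whose self-alignment has paired runs of exactly
    6, 8, 1 and 11 columns (26 pairs, 52 paired bases over the 63-base
    span) - the pinned arithmetic for the A and D worked examples.
    """
    from .align import self_ir_align

    arm5 = "GGAUAU" + "A" + "CCGGAAUU" + "A" + "A" + "A" + "GCGCAUAUAUA"
    assert len(arm5) == 29
    loop = "AAAAA"
    arm3 = list(revcomp_str(arm5))
    # break pairing at the three separator positions (arm5 indices 6, 15, 17)
    for arm5_idx in (6, 15, 17):
        j = len(arm5) - 1 - arm5_idx
        arm3[j] = "A"  # partner is A; A:A neither pairs nor wobbles
    seq = NucleotideSequence(arm5 + loop + "".join(arm3))
    aln = self_ir_align(seq)
    if aln is None or aln.run_lengths() != [6, 8, 1, 11]:
        raise AssertionError("worked example fixture no longer reproduces its runs")
    return aln
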