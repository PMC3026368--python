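import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadscan import (
    DEFAULT_SCHEME,
    MISMATCH,
    WC_MATCH,
    WOBBLE,
    NucleotideSequence,
    classify_columns,
    pairing_string,
    reverse_complement,
    self_ir_align,
)
from dyadscan.align import Column, GAP_CHAR

from .oracle import brute_self_align


def rand_seq(rng, length):
    return NucleotideSequence("".join(rng.choice(list("ACGU"), size=length)))


class TestSelfAlign:
    def test_perfect_stem(self):
        # 10 bp all-GC stem, 4 nt non-pairing loop
        seq = NucleotideSequence("G" * 10 + "AAAA" + "C" * 10)
        aln = self_ir_align(seq)
        assert (aln.score, aln.n, aln.k) == (50, 10, 10)
        assert aln.arms == ((0, 10), (14, 24))
        assert pairing_string(aln) == "((((((((((....))))))))))"

    def test_no_complementarity_returns_none(self):
        assert self_ir_align(NucleotideSequence("A" * 10)) is None

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            self_ir_align(NucleotideSequence("A"))

    def test_score_positive_contract(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            aln = self_ir_align(rand_seq(rng, 40))
            if aln is not None:
                assert aln.score > 0

    def test_arms_never_overlap(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            aln = self_ir_align(rand_seq(rng, 50))
            if aln is not None:
                (a1s, a1e), (a2s, a2e) = aln.arms
                assert a1e <= a2s

    def test_rescoring_invariant(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            aln = self_ir_align(rand_seq(rng, 60))
            if aln is not None:
                assert aln.rescore(DEFAULT_SCHEME) == aln.score

    def test_n_le_k_and_counts(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            aln = self_ir_align(rand_seq(rng, 60))
            if aln is not None:
                assert 0 <= aln.n <= aln.k == len(aln.columns)


class TestOracleEquivalence:
    def test_random_60mer_matches_brute_force(self):
        rng = np.random.default_rng(60)
        seq = rand_seq(rng, 60)
        ours = self_ir_align(seq)
        ref = brute_self_align(seq.residues)
        assert ref is not None and ours is not None
        score, qspan, tspan = ref
        assert ours.score == score
        assert (ours.q_start, ours.q_end) == qspan
        assert (ours.t_start, ours.t_end) == tspan

    def test_many_random_sequences(self):
        rng = np.random.default_rng(600)
        checked = 0
        for _ in range(60):
            length = int(rng.integers(4, 81))
            seq = rand_seq(rng, length)
            ours = self_ir_align(seq)
            ref = brute_self_align(seq.residues)
            if ref is None:
                assert ours is None
            else:
                assert ours is not None
                assert ours.score == ref[0]
                assert (ours.q_start, ours.q_end) == ref[1]
                assert (ours.t_start, ours.t_end) == ref[2]
                checked += 1
        assert checked >= 40  # almost all random sequences carry some IR

    def test_sequences_with_ns(self):
        rng = np.random.default_rng(601)
        for _ in range(20):
            s = "".join(rng.choice(list("ACGUN"), size=40))
            ours = self_ir_align(NucleotideSequence(s))
            ref = brute_self_align(s)
            if ref is None:
                assert ours is None
            else:
                assert ours is not None and ours.score == ref[0]


class TestStrandSymmetry:
    # A G.U wobble on the forward strand is an A.C opposition on the
    # reverse strand, so the default -2 wobble entries make optimal scores
    # strand-dependent by design.  Exact strand symmetry holds for a
    # wobble-free scheme, and wobbles can only ever change scores by the
    # wobble/mismatch differential.

    @staticmethod
    def _wobble_free():
        sub = DEFAULT_SCHEME.substitution.copy()
        sub[2, 0] = -4  # G vs A
        sub[3, 1] = -4  # U vs C
        from dyadscan import ScoringScheme

        return ScoringScheme(substitution=sub)

    def test_equal_scores_without_wobble(self):
        scheme = self._wobble_free()
        rng = np.random.default_rng(21)
        for _ in range(50):
            seq = rand_seq(rng, 50)
            fwd = self_ir_align(seq, scheme)
            rev = self_ir_align(reverse_complement(seq), scheme)
            if fwd is None:
                assert rev is None
            else:
                assert rev is not None and rev.score == fwd.score

    def test_default_scheme_scores_close(self):
        rng = np.random.default_rng(22)
        for _ in range(50):
            seq = rand_seq(rng, 50)
            fwd = self_ir_align(seq)
            rev = self_ir_align(reverse_complement(seq))
            fs = 0 if fwd is None else fwd.score
            rs = 0 if rev is None else rev.score
            # differ by at most the wobble differential per wobble column
            assert abs(fs - rs) <= 2 * max(fwd.k if fwd else 0, rev.k if rev else 0)


class TestPlantedStemRecovery:
    @pytest.mark.parametrize("seed,stem", [(1, 10), (2, 15), (3, 20)])
    def test_perfect_stem_recovered(self, seed, stem):
        rng = np.random.default_rng(seed)
        arm = "".join(rng.choice(list("ACGU"), size=stem))
        comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
        hairpin = arm + "AACAA" + "".join(comp[c] for c in reversed(arm))
        bg = "".join(rng.choice(list("ACGU"), size=200 - len(hairpin)))
        seq = NucleotideSequence(bg[:80] + hairpin + bg[80:])
        aln = self_ir_align(seq)
        assert aln is not None
        assert aln.n >= stem  # the planted stem dominates


class TestClassification:
    def test_identical_letters_are_wc(self):
        col = Column("G", "G", MISMATCH)
        aln = _one_column_aln(col)
        classify_columns(aln)
        assert col.cls == WC_MATCH

    def test_g_vs_a_is_wobble(self):
        col = Column("G", "A", MISMATCH)
        classify_columns(_one_column_aln(col))
        assert col.cls == WOBBLE

    def test_u_vs_c_is_wobble(self):
        col = Column("U", "C", MISMATCH)
        classify_columns(_one_column_aln(col))
        assert col.cls == WOBBLE

    def test_a_vs_c_is_mismatch(self):
        col = Column("A", "C", WC_MATCH)
        classify_columns(_one_column_aln(col))
        assert col.cls == MISMATCH

    def test_nn_is_not_a_pair(self):
        col = Column("N", "N", WC_MATCH)
        classify_columns(_one_column_aln(col))
        assert col.cls == MISMATCH

    def test_gap_column(self):
        col = Column("A", GAP_CHAR, WC_MATCH)
        classify_columns(_one_column_aln(col))
        assert col.cls == "GAP"


def _one_column_aln(col):
    from dyadscan.align import IRAlignment

    seq = NucleotideSequence("ACGUACGU")
    return IRAlignment(seq=seq, q_start=0, q_end=1, t_start=0, t_end=1, score=1, columns=[col])


class TestPairingString:
    def test_all_paired_stem_with_loop(self):
        seq = NucleotideSequence("GCGCGC" + "AAA" + "GCGCGC")
        aln = self_ir_align(seq)
        assert pairing_string(aln) == "((((((...))))))"

    def test_mismatch_dots_mirror(self):
        s = pairing_string_of_central_mismatch()
        open_part, close_part = s.split("...")
        assert open_part == "((.((" and close_part == ")).))"

    def test_balanced(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            aln = self_ir_align(rand_seq(rng, 60))
            if aln is not None:
                s = pairing_string(aln)
                assert s.count("(") == s.count(")") == aln.n
                depth = 0
                for ch in s:
                    depth += {"(": 1, ")": -1}.get(ch, 0)
                    assert depth >= 0
                assert depth == 0

    def test_empty_alignment_errors(self):
        from dyadscan.align import IRAlignment

        aln = IRAlignment(
            seq=NucleotideSequence("ACGU"), q_start=0, q_end=0, t_start=0, t_end=0,
            score=0, columns=[],
        )
        with pytest.raises(ValueError):
            pairing_string(aln)


def pairing_string_of_central_mismatch():
    # 5-column arms with the middle pair broken: the A:A opposition neither
    # pairs nor wobbles, so both sides show a dot
    seq = NucleotideSequence("GGAGG" + "AAA" + "CCACC")
    aln = self_ir_align(seq)
    return pairing_string(aln)


@settings(max_examples=40, deadline=None)
@given(st.text(alphabet="ACGU", min_size=4, max_size=40))
def test_property_rescore_and_balance(s):
    aln = self_ir_align(NucleotideSequence(s))
    if aln is None:
        return
    assert aln.rescore(DEFAULT_SCHEME) == aln.score
    ps = pairing_string(aln)
    assert ps.count("(") == ps.count(")")
    assert len(ps) == aln.span_length
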