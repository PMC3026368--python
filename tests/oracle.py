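"""Independent brute-force references used by the test suite.

Deliberately naive: full matrices kept in plain Python lists, traceback by
re-derivation instead of stored pointers, enumeration instead of closed
forms.  Nothing here imports the implementation's alignment or statistics
code paths.
"""

from fractions import Fraction
from math import comb

_SCORE = {}
for _i, _a in enumerate("ACGUN"):
    for _j, _b in enumerate("ACGUN"):
        row = [
            [5, -4, -4, -4, 0],
            [-4, 5, -4, -4, 0],
            [-2, -4, 5, -4, 0],
            [-4, -2, -4, 5, 0],
            [0, 0, 0, 0, 3],
        ][_i]
        _SCORE[(_a, _b)] = row[_j]

GAP = -6

_COMP = {"A": "U", "C": "G", "G": "C", "U": "A", "N": "N"}


def brute_revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def brute_self_align(seq: str):
    """Best local alignment of seq vs its reverse complement, rejecting
    end cells whose traceback arms overlap on the original sequence.

    Returns (score, (q_start, q_end), (t_start, t_end)) or None.
    Tie-breaks: smallest (row, col) end cell; diagonal > up > left.
    """
    t = brute_revcomp(seq)
    L = len(seq)
    n, m = len(seq), len(t)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            H[i][j] = max(
                0,
                H[i - 1][j - 1] + _SCORE[(seq[i - 1], t[j - 1])],
                H[i - 1][j] + GAP,
                H[i][j - 1] + GAP,
            )

    cells = [
        (i, j) for i in range(1, n + 1) for j in range(1, m + 1) if H[i][j] > 0
    ]
    cells.sort(key=lambda c: (-H[c[0]][c[1]], c[0], c[1]))

    for i, j in cells:
        ci, cj = i, j
        while H[ci][cj] != 0:
            # re-derive the pointer: diagonal preferred, then up, then left
            if (
                ci > 0
                and cj > 0
                and H[ci][cj] == H[ci - 1][cj - 1] + _SCORE[(seq[ci - 1], t[cj - 1])]
            ):
                ci, cj = ci - 1, cj - 1
            elif ci > 0 and H[ci][cj] == H[ci - 1][cj] + GAP:
                ci -= 1
            else:
                cj -= 1
        q_arm = (ci, i)
        t_arm_on_orig = (L - j, L - cj)
        if max(q_arm[0], t_arm_on_orig[0]) < min(q_arm[1], t_arm_on_orig[1]):
            continue  # arms overlap; not a hairpin
        return H[i][j], q_arm, (cj, j)
    return None


def brute_probability(n: int, k: int) -> Fraction:
    """Exact rational P(n, k) = C(k, n) * 1^n * 3^(k-n) / 4^k."""
    return Fraction(comb(k, n) * 3 ** (k - n), 4**k)


def enumerate_probability(n: int, k: int) -> Fraction:
    """P(n, k) by enumerating all 4^(2k) (LHS, RHS) arm pairs and counting
    those whose reverse-complement positions match at exactly n places."""
    import itertools

    bases = "ACGU"
    total = 0
    hits = 0
    for lhs in itertools.product(bases, repeat=k):
        for rhs in itertools.product(bases, repeat=k):
            matches = sum(
                1 for i in range(k) if rhs[k - 1 - i] == _COMP[lhs[i]]
            )
            total += 1
            if matches == n:
                hits += 1
    return Fraction(hits, total)


def enumerate_probability_fast(n: int, k: int) -> Fraction:
    """Same enumeration, vectorised so k = 5 stays under a few seconds."""
    import numpy as np

    # every (lhs, rhs) pair is a 2k-digit base-4 integer; position i of the
    # LHS matches when rhs digit (k-1-i) equals the complement of lhs digit i
    comp = np.array([3, 2, 1, 0])  # A<->U, C<->G in digit space
    idx = np.arange(4 ** (2 * k), dtype=np.int64)
    matches = np.zeros_like(idx)
    for i in range(k):
        lhs_digit = (idx >> np.int64(2 * (2 * k - 1 - i))) & 3
        rhs_digit = (idx >> np.int64(2 * (k - 1 - (k - 1 - i)))) & 3
        matches += comp[lhs_digit] == rhs_digit
    hits = int((matches == n).sum())
    return Fraction(hits, 4 ** (2 * k))
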