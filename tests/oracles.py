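"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the alignment oracle is a
plain three-state dynamic program, and the Fisher oracle enumerates the full
hypergeometric support with exact rational arithmetic.
"""
from fractions import Fraction
from math import comb

import numpy as np


def gotoh_score(s1: str, s2: str, match=1.0, mismatch=-1.0,
                open_=-4.0, extend=-1.0) -> float:
    """Affine-gap global alignment optimum (gap of length k costs
    open + (k-1)*extend; end gaps penalized)."""
    n, m = len(s1), len(s2)
    neg = float("-inf")
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in s2 (consumes s1)
    Y = np.full((n + 1, m + 1), neg)  # gap in s1 (consumes s2)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Y[0][j] = open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if s1[i - 1] == s2[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1],
                              Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend,
                          Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend,
                          X[i][j - 1] + open_)
    return max(M[n][m], X[n][m], Y[n][m])


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher P by full enumeration over the fixed-margin support.

    Sums the exact (rational) probabilities of all tables whose probability
    does not exceed the observed table's.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denominator = comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denominator)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        p = Fraction(comb(r1, x) * comb(r2, c1 - x), denominator)
        if p <= p_obs:
            total += p
    return float(total)
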