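"""Independent oracles used by the test suite.

These deliberately avoid the implementation's code paths: exact rational
arithmetic for the two count tests, closed forms plus ``math.erfc`` for the
chi-square tail, explicit enumeration of nested pairings for folding, and a
rank-then-Pearson route for the Spearman coefficient.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

PAIR_W = {("G", "C"): 3, ("C", "G"): 3, ("A", "T"): 2, ("T", "A"): 2, ("G", "T"): 1, ("T", "G"): 1}


def audic_claverie_oracle(x: int, y: int, n1: int, n2: int, sided: str = "two") -> float:
    """Exact-rational evaluation of the conditional count distribution.

    p(k | x) = r^k (x+k)! / (x! k!) / (1+r)^(x+k+1) with r = N2/N1, summed
    term by term with Fractions.
    """
    r = Fraction(n2, n1)
    pk = Fraction(1) / (1 + r) ** (x + 1)  # p(0 | x)
    lower = Fraction(0)
    p_y = pk
    for k in range(0, y + 1):
        p_y = pk
        lower += pk
        pk = pk * r * (x + k + 1) / ((k + 1) * (1 + r))
    upper = 1 - lower + p_y  # P(Y >= y)
    if sided == "less":
        return float(min(Fraction(1), lower))
    if sided == "greater":
        return float(min(Fraction(1), upper))
    return float(min(Fraction(1), 2 * min(lower, upper)))


def fisher_exact_oracle(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration with exact rationals.

    Fixed margins: first column x+y, rows n1 and n2. Sums P(k) over all
    admissible tables whose probability is at most the observed one (with
    the same 1e-7 relative gate the float implementations use for ties).
    """
    col1 = x + y
    total = n1 + n2
    denom = math.comb(total, n1)
    lo = max(0, col1 - n2)
    hi = min(col1, n1)
    probs = {
        k: Fraction(math.comb(col1, k) * math.comb(total - col1, n1 - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = probs[x]
    gate = p_obs * (1 + Fraction(1, 10**7))
    return float(min(Fraction(1), sum(p for p in probs.values() if p <= gate)))


def chi_square_oracle(x: int, y: int, n1: int, n2: int) -> float:
    """Closed-form 2x2 statistic with the erfc route for the 1-df tail."""
    a, b, c, d = x, n1 - x, y, n2 - y
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        return 1.0
    stat = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return math.erfc(math.sqrt(stat / 2.0))


def best_nested_score(seq: str, min_loop: int = 3) -> int:
    """Maximum pair-weight over all nested pairings, by explicit enumeration.

    Recursion over the leftmost position: leave it unpaired, or pair it with
    every admissible partner and recurse independently inside and outside.
    Exponential, fine for n <= 12.
    """
    seq = seq.upper().replace("U", "T")

    def rec(lo: int, hi: int) -> int:  # half-open [lo, hi)
        if hi - lo < min_loop + 2:
            return 0
        best = rec(lo + 1, hi)
        for j in range(lo + min_loop + 1, hi):
            w = PAIR_W.get((seq[lo], seq[j]), 0)
            if w:
                best = max(best, w + rec(lo + 1, j) + rec(j + 1, hi))
        return best

    return rec(0, len(seq))


def spearman_oracle(a, b) -> float:
    """Average-rank transform followed by a textbook Pearson computation."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v), dtype=float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    ra, rb = ranks(a), ranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra * rb).sum() / math.sqrt((ra**2).sum() * (rb**2).sum()))
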