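"""Independent exact-arithmetic / brute-force oracles used by the tests.

Everything here is computed with rational arithmetic or naive
enumeration, deliberately sharing no code path with the package.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def exact_p_term(i: int, x: int, n2_over_n1: Fraction) -> Fraction:
    """p(i|x) as an exact rational: r^i C(x+i, i) (1+r)^-(x+i+1)."""
    r = Fraction(n2_over_n1)
    return r**i * comb(x + i, i) * (1 + r) ** -(x + i + 1)


def exact_cum(x: int, y: int, n2_over_n1: Fraction) -> Fraction:
    """Exact cumulative sum S = sum_{i=0}^{y} p(i|x)."""
    r = Fraction(n2_over_n1)
    term = (1 + r) ** -(x + 1)  # p(0|x)
    total = term
    for i in range(y):
        term = term * r * (x + i + 1) / ((i + 1) * (1 + r))
        total += term
    return total


def exact_two_sided(x: int, y: int, n2_over_n1: Fraction) -> Fraction:
    s = exact_cum(x, y, n2_over_n1)
    p = 2 * s if s <= Fraction(1, 2) else 2 * (1 - s)
    return min(max(p, Fraction(0)), Fraction(1))


def exact_hypergeom_upper(k: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= k) by exact enumeration of the hypergeometric mass."""
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return total


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
         "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
         "D": "H", "H": "D", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def sliding_window_hits(seq: str, pattern: str, both_strands: bool = True):
    """All (start, end, strand) matches of an IUPAC pattern, naively."""
    hits = []
    for strand in ("+", "-") if both_strands else ("+",):
        pat = pattern if strand == "+" else revcomp(pattern)
        w = len(pat)
        for s in range(len(seq) - w + 1):
            if all(seq[s + j] in _IUPAC[pat[j]] for j in range(w)):
                hits.append((s, s + w, strand))
    return sorted(hits)
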