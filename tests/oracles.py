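"""Independent brute-force oracles used by the test suite.

Deliberately written from scratch with exact rational arithmetic and a
hardcoded genetic code, sharing no code path with the package.
"""

from fractions import Fraction
from itertools import combinations, permutations
from math import comb

_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
ORACLE_CODE = {}
_i = 0
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            ORACLE_CODE[_b1 + _b2 + _b3] = _AAS[_i]
            _i += 1


def oracle_codon_sites(codon):
    """(S, N) for one codon as exact Fractions; stop mutations excluded
    from each position's denominator."""
    aa = ORACLE_CODE[codon]
    S = Fraction(0)
    for pos in range(3):
        syn, viable = 0, 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if ORACLE_CODE[mut] == "*":
                continue
            viable += 1
            if ORACLE_CODE[mut] == aa:
                syn += 1
        if viable:
            S += Fraction(syn, viable)
    return S, 3 - S


def oracle_pathway_diffs(c1, c2):
    """(Sd, Nd) for one codon pair by explicit pathway enumeration."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return Fraction(0), Fraction(0)
    all_paths = []
    for order in permutations(diffs):
        cur, steps, through_stop = c1, [], False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if ORACLE_CODE[nxt] == "*":
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        all_paths.append((through_stop, steps))
    usable = [s for blocked, s in all_paths if not blocked]
    if not usable:
        usable = [s for _, s in all_paths]
    Sd = Nd = Fraction(0)
    for steps in usable:
        for before, after in steps:
            if ORACLE_CODE[before] == ORACLE_CODE[after]:
                Sd += 1
            else:
                Nd += 1
    n = len(usable)
    return Sd / n, Nd / n


def oracle_ng86(seq_a, seq_b):
    """Exact (S, N, Sd, Nd) for a codon-aligned pair."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    S = N = Sd = Nd = Fraction(0)
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        sa, na = oracle_codon_sites(ca)
        sb, nb = oracle_codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = oracle_pathway_diffs(ca, cb)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def oracle_hypergeom_upper(k, K, n, N):
    """P(X >= k) by exact binomial-coefficient summation (Fraction)."""
    total = comb(N, n)
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return Fraction(num, total)


def oracle_hypergeom_by_enumeration(k, K, n, N):
    """P(X >= k) by enumerating every possible draw of n from N items."""
    items = list(range(N))
    successes = set(items[:K])
    hits = total = 0
    for draw in combinations(items, n):
        total += 1
        if sum(1 for x in draw if x in successes) >= k:
            hits += 1
    return Fraction(hits, total)
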