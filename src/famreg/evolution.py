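"""Nei-Gojobori (1986) Ka/Ks on codon-aligned pairs and clock dating.

Site counting enumerates the 9 single-base changes per codon; mutations
that would create a stop codon are excluded from a position's
denominator, so every position still contributes one full site and
S + N equals the alignment length in nucleotides. Codons differing at
more than one position are resolved by unweighted averaging over all
substitution pathways that avoid stop codons, each pathway step
classified synonymous or nonsynonymous. Proportions are corrected with
the Jukes-Cantor formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

MONOCOT_LAMBDA = 6.5e-9
DICOT_LAMBDA = 1.5e-8

_BASES = "ACGT"

#: codon -> amino acid, with '*' for stops (standard nuclear code only).
GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    GENETIC_CODE[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)


@dataclass(frozen=True)
class CodonPairAlignment:
    """Gap-free codon alignment of two near-identical paralog CDSs."""

    seq_a: str
    seq_b: str
    id_a: str = "a"
    id_b: str = "b"

    def __post_init__(self):
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError("aligned sequences differ in length")
        if len(a) % 3 != 0:
            raise ValueError("alignment length not a multiple of 3")
        for name, seq in ((self.id_a, a), (self.id_b, b)):
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if codon in STOP_CODONS:
                    raise ValueError(f"internal stop codon in {name} at nt {i + 1}")
                if codon not in GENETIC_CODE:
                    raise ValueError(f"non-ACGT codon {codon!r} in {name}")

    def codons(self) -> list[tuple[str, str]]:
        return [
            (self.seq_a[i : i + 3], self.seq_b[i : i + 3])
            for i in range(0, len(self.seq_a), 3)
        ]


@dataclass(frozen=True)
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    ratio: float | None
    T_mya: float | None = None


def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Each of the 3 positions contributes one site, split by the fraction
    of its non-stop single-base changes that are synonymous.
    """
    aa = GENETIC_CODE[codon]
    syn_sites = 0.0
    for pos in range(3):
        syn = 0
        viable = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            viable += 1
            if GENETIC_CODE[mutant] == aa:
                syn += 1
        syn_sites += syn / viable if viable else 0.0
    return syn_sites, 3.0 - syn_sites


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts for one codon pair.

    Averages over all orderings of the differing positions; orderings
    that pass through a stop codon are discarded (unless every ordering
    does, in which case all are kept so the differences are not lost).
    """
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    k = len(diff_positions)
    if k == 0:
        return 0.0, 0.0
    if k == 1:
        pos = diff_positions[0]
        mutant = c1[:pos] + c2[pos] + c1[pos + 1 :]
        if GENETIC_CODE[c1] == GENETIC_CODE[mutant]:
            return 1.0, 0.0
        return 0.0, 1.0
    pathways = []
    for order in permutations(diff_positions):
        current = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((current, nxt))
            current = nxt
        pathways.append((blocked, steps))
    usable = [steps for blocked, steps in pathways if not blocked]
    if not usable:
        usable = [steps for _, steps in pathways]
    syn = nonsyn = 0.0
    for steps in usable:
        for before, after in steps:
            if GENETIC_CODE[before] == GENETIC_CODE[after]:
                syn += 1.0
            else:
                nonsyn += 1.0
    n = len(usable)
    return syn / n, nonsyn / n


def ng86_counts(aln: CodonPairAlignment) -> tuple[float, float, float, float]:
    """NG86 site and difference counts (S, N, Sd, Nd).

    S and N are averaged over the two sequences; Sd and Nd sum the
    pathway-averaged per-codon difference counts.
    """
    S = N = Sd = Nd = 0.0
    for ca, cb in aln.codons():
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def jukes_cantor(p: float) -> float | None:
    """JC-corrected substitution rate, or None when saturated (4p/3 >= 1)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return None
    return -0.75 * math.log(arg)


def kaks(aln: CodonPairAlignment) -> KaKsResult:
    """Full NG86 Ka/Ks for one codon-aligned pair.

    Saturated or zero-denominator quantities are returned as None; the
    raw proportions are always populated.
    """
    S, N, Sd, Nd = ng86_counts(aln)
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS) if S > 0 else None
    Ka = jukes_cantor(pN) if N > 0 else None
    if Ka is None or Ks is None or Ks == 0.0:
        ratio = None
    else:
        ratio = Ka / Ks
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka, ratio=ratio)


def divergence_time(ks: float, rate_lambda: float) -> float:
    """Divergence time T = Ks / (2 * lambda), reported in mya."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    if rate_lambda <= 0:
        raise ValueError("substitution rate must be positive")
    return ks / (2.0 * rate_lambda) / 1e6


def pair_codon_alignment(seq_a: str, seq_b: str, id_a: str = "a", id_b: str = "b") -> CodonPairAlignment:
    """Ungapped codon matcher for equal-length CDSs (near-identical paralogs)."""
    if len(seq_a) != len(seq_b):
        raise ValueError("ungapped codon matching requires equal-length CDSs")
    return CodonPairAlignment(seq_a, seq_b, id_a, id_b)
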