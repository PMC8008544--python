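"""Strand-aware promoter extraction and cis-regulatory-element scanning.

Promoter coordinate system: position +1 is the TSS base, upstream
positions are negative, and there is no position 0. The default window
spans -2000..+1, i.e. 2001 nt including the TSS base.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .genome_io import IUPAC_SETS, GeneModel, revcomp

E2FAT_PATTERN = "TTTCCCGCC"


@dataclass(frozen=True)
class PromoterRegion:
    """Extracted upstream window, read 5'->3' relative to its gene.

    For - strand genes ``seq`` is the reverse complement of the genomic
    slice, so motif scanning works identically on both strands.
    """

    gene_id: str
    seq: str
    genomic_interval: tuple[int, int]
    strand: str
    truncated: bool = False

    def tss_relative(self, index: int) -> int:
        """Map a 0-based index into ``seq`` to a TSS-relative position.

        The last base of ``seq`` is the TSS base (+1); positions upstream
        are negative and position 0 does not exist.
        """
        d = (len(self.seq) - 1) - index
        return 1 if d == 0 else -d


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif_id: str
    tss_relative_start: int
    strand_of_match: str
    matched_seq: str


@dataclass(frozen=True)
class CreEntry:
    motif_id: str
    pattern: str
    category: str


CRE_CATEGORIES = {"light", "hormone", "TF-binding", "meristem", "other"}

#: Illustrative CRE dictionary; patterns are user-replaceable, not canonical.
DEFAULT_CRE_DICTIONARY: tuple[CreEntry, ...] = (
    CreEntry("E2FAT", E2FAT_PATTERN, "TF-binding"),
    CreEntry("ABRE", "ACGTGGC", "hormone"),
    CreEntry("TGACG-motif", "TGACG", "hormone"),
    CreEntry("TCA-element", "CCATCTTTTT", "hormone"),
    CreEntry("P-box", "CCTTTTG", "hormone"),
    CreEntry("GARE-motif", "TCTGTTG", "hormone"),
    CreEntry("CAT-box", "GCCACT", "meristem"),
    CreEntry("MYB", "WAACCA", "TF-binding"),
    CreEntry("MYC", "CANNTG", "TF-binding"),
    CreEntry("G-box", "CACGTG", "light"),
    CreEntry("GT1-motif", "GGTTAA", "light"),
    CreEntry("Box4", "ATTAAT", "light"),
)


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC pattern into a regex over concrete A/C/G/T.

    Ambiguity codes in the *pattern* expand to character classes; N or any
    ambiguity code in the *sequence* never matches (classes contain only
    concrete bases).
    """
    if not pattern:
        raise ValueError("empty motif pattern")
    parts = []
    for ch in pattern.upper():
        try:
            bases = IUPAC_SETS[ch]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern") from None
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping matches are all reported
    return re.compile("(?=(" + "".join(parts) + "))")


def extract_promoter(
    genome: dict[str, str], model: GeneModel, upstream_len: int = 2000
) -> PromoterRegion:
    """Extract the -upstream_len..+1 window for one gene.

    + strand: genomic [tss-upstream_len, tss]; - strand: genomic
    [tss, tss+upstream_len] reverse-complemented. Windows running off a
    contig end are clipped and flagged ``truncated``.
    """
    if model.chrom not in genome:
        raise KeyError(f"{model.gene_id}: chromosome {model.chrom} not in genome")
    chrom_seq = genome[model.chrom]
    chrom_len = len(chrom_seq)
    tss = model.tss
    if not 1 <= tss <= chrom_len:
        raise ValueError(
            f"{model.gene_id}: TSS {tss} outside chromosome of length {chrom_len}"
        )
    if model.strand == "+":
        start = max(1, tss - upstream_len)
        end = tss
        seq = chrom_seq[start - 1 : end]
        truncated = tss - upstream_len < 1
    else:
        start = tss
        end = min(chrom_len, tss + upstream_len)
        seq = revcomp(chrom_seq[start - 1 : end])
        truncated = tss + upstream_len > chrom_len
    return PromoterRegion(
        gene_id=model.gene_id,
        seq=seq,
        genomic_interval=(start, end),
        strand=model.strand,
        truncated=truncated,
    )


def scan_motif(
    promoter: PromoterRegion,
    motif_id: str,
    pattern: str,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Find all occurrences of an IUPAC pattern in a promoter.

    Matches on the promoter's own orientation are reported with
    strand_of_match '+'; matches of the reverse complement of the pattern
    (i.e. a site on the opposite physical strand) with '-'. Overlapping
    matches are all reported.
    """
    hits = []
    rx = iupac_regex(pattern)
    for m in rx.finditer(promoter.seq):
        i = m.start()
        hits.append(
            MotifHit(
                gene_id=promoter.gene_id,
                motif_id=motif_id,
                tss_relative_start=promoter.tss_relative(i),
                strand_of_match="+",
                matched_seq=m.group(1),
            )
        )
    if both_strands:
        rc = revcomp(pattern)
        if rc != pattern:  # palindromes would double-count
            rx_rc = iupac_regex(rc)
            for m in rx_rc.finditer(promoter.seq):
                i = m.start()
                hits.append(
                    MotifHit(
                        gene_id=promoter.gene_id,
                        motif_id=motif_id,
                        tss_relative_start=promoter.tss_relative(i),
                        strand_of_match="-",
                        matched_seq=m.group(1),
                    )
                )
    hits.sort(key=lambda h: (h.tss_relative_start, h.strand_of_match))
    return hits


def find_target_genes(
    promoters: list[PromoterRegion],
    e2fat_pattern: str = E2FAT_PATTERN,
    both_strands: bool = True,
) -> list[str]:
    """Genes with >= 1 binding-site hit in their promoter, sorted by id."""
    targets = set()
    for prom in promoters:
        if scan_motif(prom, "E2FAT", e2fat_pattern, both_strands=both_strands):
            targets.add(prom.gene_id)
    return sorted(targets)


def count_cres(
    promoters: list[PromoterRegion],
    dictionary: tuple[CreEntry, ...] = DEFAULT_CRE_DICTIONARY,
    min_total: int = 5,
    both_strands: bool = True,
):
    """Per-gene per-motif CRE hit counts.

    Returns ``(raw, filtered)`` where each is {motif_id: {gene_id: count}};
    ``filtered`` drops motifs whose genome-wide total is <= min_total
    (i.e. only motifs with total strictly greater than min_total are
    retained).
    """
    if not dictionary:
        raise ValueError("empty CRE dictionary")
    raw: dict[str, dict[str, int]] = {}
    for entry in dictionary:
        counts = {}
        for prom in promoters:
            n = len(scan_motif(prom, entry.motif_id, entry.pattern, both_strands))
            if n:
                counts[prom.gene_id] = n
        raw[entry.motif_id] = counts
    filtered = {
        motif: counts
        for motif, counts in raw.items()
        if sum(counts.values()) > min_total
    }
    return raw, filtered
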