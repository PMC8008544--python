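"""Domain-architecture classification, gene-structure stats, tandem screen."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .genome_io import DomainAnnotation, GeneModel

FAMILY_DOMAINS = {"E2F_TD", "E2F_DD", "DP", "MarkedBox", "RBR_binding"}
GROUPS = ("E2F", "DP", "DEL", "partial", "unclassified")

DEFAULT_EVALUE_CUTOFF = 1e-5
#: overlap below this fraction of the shorter hit counts as non-overlapping
OVERLAP_FRACTION = 0.20


@dataclass(frozen=True)
class FamilyAssignment:
    gene_id: str
    group: str
    evidence: tuple[str, ...] = ()


def _overlap_fraction(a: DomainAnnotation, b: DomainAnnotation) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return 0.0
    shorter = min(a.end - a.start + 1, b.end - b.start + 1)
    return ov / shorter


def _collapse(hits: list[DomainAnnotation]) -> list[DomainAnnotation]:
    """Drop same-domain hits overlapping >= OVERLAP_FRACTION of the shorter.

    Keeps the best e-value representative so duplicated fragments of one
    underlying domain are not double-counted.
    """
    kept: list[DomainAnnotation] = []
    for hit in sorted(hits, key=lambda h: (h.evalue, h.start, h.end)):
        if any(
            h.domain_name == hit.domain_name
            and _overlap_fraction(h, hit) >= OVERLAP_FRACTION
            for h in kept
        ):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: (h.start, h.end, h.domain_name))
    return kept


def classify_architecture(
    domains: list[DomainAnnotation],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> FamilyAssignment:
    """Classify one protein's hit set into E2F / DP / DEL / partial.

    Rule order: (1) two non-overlapping DNA-binding (E2F_TD) hits and no
    DP domain -> DEL; (2) E2F_TD plus dimerization (E2F_DD) domain -> E2F;
    (3) DP domain present -> DP; (4) any remaining family hit -> partial;
    (5) otherwise unclassified. Pure function of the hit set.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    protein_ids = {h.protein_id for h in domains}
    if len(protein_ids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(protein_ids)}")
    gene_id = domains[0].protein_id if domains else ""
    hits = _collapse([h for h in domains if h.evalue <= evalue_cutoff])
    names = {h.domain_name for h in hits if h.domain_name in FAMILY_DOMAINS}

    td_hits = [h for h in hits if h.domain_name == "E2F_TD"]
    has_distinct_tds = any(
        _overlap_fraction(a, b) < OVERLAP_FRACTION
        for i, a in enumerate(td_hits)
        for b in td_hits[i + 1 :]
    )
    if has_distinct_tds and "DP" not in names:
        return FamilyAssignment(gene_id, "DEL", ("E2F_TD", "E2F_TD"))
    if "E2F_TD" in names and "E2F_DD" in names:
        return FamilyAssignment(gene_id, "E2F", tuple(sorted(names)))
    if "DP" in names:
        return FamilyAssignment(gene_id, "DP", tuple(sorted(names)))
    if names:
        return FamilyAssignment(gene_id, "partial", tuple(sorted(names)))
    return FamilyAssignment(gene_id, "unclassified", ())


def classify_all(
    domains: list[DomainAnnotation],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> list[FamilyAssignment]:
    """Group a mixed domain table by protein and classify each one."""
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for hit in domains:
        by_protein.setdefault(hit.protein_id, []).append(hit)
    return [
        classify_architecture(hits, evalue_cutoff)
        for _, hits in sorted(by_protein.items())
    ]


def intron_stats(
    models: list[GeneModel],
    assignments: list[FamilyAssignment],
) -> dict[str, dict[str, float]]:
    """Per-group min/max/mean intron counts (introns = exons - 1)."""
    group_of = {a.gene_id: a.group for a in assignments}
    per_group: dict[str, list[int]] = {}
    for model in models:
        if len(model.exons) == 0:
            warnings.warn(f"{model.gene_id}: zero exons, excluded from intron stats")
            continue
        group = group_of.get(model.gene_id)
        if group is None:
            continue
        per_group.setdefault(group, []).append(model.n_introns)
    return {
        group: {
            "min": float(min(counts)),
            "max": float(max(counts)),
            "mean": sum(counts) / len(counts),
            "n": float(len(counts)),
        }
        for group, counts in sorted(per_group.items())
    }


def detect_tandem(
    assignments: list[FamilyAssignment],
    models: list[GeneModel],
    max_intervening: int = 10,
    max_distance_bp: int = 200_000,
) -> list[tuple[str, str]]:
    """Screen for tandem-duplicated family members.

    A pair is tandem iff both genes belong to the family (any group but
    unclassified), lie on the same chromosome, and are separated by at
    most ``max_intervening`` non-family genes AND ``max_distance_bp``
    (gap between gene spans). ``models`` must cover every family gene.
    """
    family = {a.gene_id for a in assignments if a.group != "unclassified"}
    known = {m.gene_id for m in models}
    missing = family - known
    if missing:
        raise ValueError(f"family genes missing from gene order: {sorted(missing)}")
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    pairs = []
    for chrom, chrom_models in sorted(by_chrom.items()):
        chrom_models.sort(key=lambda m: m.gene_span)
        fam_idx = [i for i, m in enumerate(chrom_models) if m.gene_id in family]
        for a_pos, i in enumerate(fam_idx):
            for j in fam_idx[a_pos + 1 :]:
                intervening = sum(
                    1
                    for k in range(i + 1, j)
                    if chrom_models[k].gene_id not in family
                )
                if intervening > max_intervening:
                    continue
                gap = chrom_models[j].gene_span[0] - chrom_models[i].gene_span[1]
                if gap > max_distance_bp:
                    continue
                pairs.append((chrom_models[i].gene_id, chrom_models[j].gene_id))
    return sorted(pairs)
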