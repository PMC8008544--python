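"""Seeded synthetic inputs with exact ground truth for every stage.

Design notes:

* Promoter windows are laid out so they never overlap (inter-gene gaps
  exceed twice the promoter length); each window's background is drawn
  by rejection sampling until, with the planted sites written in, an
  independent re-scan finds exactly the planted occurrences. Truth is
  therefore exact by construction, not by post-hoc masking.
* Expression profiles start from log-normal base signal (FPKM-like
  skew). Profiles of non-edge gene pairs are rejection-sampled to keep
  |r| <= 0.8 against every regulator, so at noise_sd=0 the planted edge
  set is exactly the set passing the 0.90 rule.
* All randomness flows from one numpy Generator seeded by the config.
"""

from __future__ import annotations

import hashlib
import json
import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .evolution import GENETIC_CODE, STOP_CODONS, codon_sites
from .genome_io import revcomp, write_fasta
from .promoter_cre import E2FAT_PATTERN

#: the 13 default condition labels (culm-tissue style)
DEFAULT_CONDITIONS = (
    "S1", "S2", "S3", "S4", "S5", "S6", "S7", "CK", "SS1", "SS2", "L", "R", "O",
)

_MAX_PROMOTER_RETRIES = 500
_MAX_PROFILE_RETRIES = 2000
_PROFILE_R_CAP = 0.80  # max |r| allowed between non-edge pairs at noise 0


@dataclass(frozen=True)
class SynthConfig:
    n_chroms: int = 2
    n_genes: int = 30
    promoter_len: int = 2000
    n_planted_e2fat: int = 20
    n_tf: int = 4
    n_targets: int = 15
    n_true_edges: int = 10
    n_conditions: int = 13
    noise_sd: float = 0.0
    paralog_ds_targets: tuple[float, ...] = (0.1, 0.2, 0.4)
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_chroms, self.n_genes, self.promoter_len,
            self.n_planted_e2fat, self.n_tf, self.n_targets,
            self.n_true_edges, self.n_conditions,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for ds in self.paralog_ds_targets:
            if not 0 < ds < 0.7:
                raise ValueError(f"paralog ds target {ds} outside (0, 0.7)")
        if self.n_tf + self.n_targets > self.n_genes:
            raise ValueError("n_tf + n_targets exceeds n_genes")
        if self.n_true_edges > 0:
            if self.n_tf == 0:
                raise ValueError("true edges require at least one TF")
            if self.n_true_edges > min(self.n_targets, self.n_planted_e2fat):
                raise ValueError(
                    "n_true_edges exceeds motif-carrying target capacity"
                )


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery scoring."""

    planted_motif_hits: list[tuple[str, int, str]] = field(default_factory=list)
    true_edges: list[tuple[str, str, str]] = field(default_factory=list)
    planted_ds: dict[str, float] = field(default_factory=dict)
    enriched_term: str = ""
    tissue_max: dict[str, str] = field(default_factory=dict)
    tf_ids: list[str] = field(default_factory=list)
    target_ids: list[str] = field(default_factory=list)
    tf_groups: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _scan_both(window: str, pattern: str) -> set[tuple[int, str]]:
    """Independent occurrence scan: (0-based index, strand) on both strands."""
    hits = set()
    for m in re.finditer(f"(?=({pattern}))", window):
        hits.add((m.start(), "+"))
    rc = revcomp(pattern)
    if rc != pattern:
        for m in re.finditer(f"(?=({rc}))", window):
            hits.add((m.start(), "-"))
    return hits


def _build_promoter_window(
    rng: np.random.Generator,
    promoter_len: int,
    tss_base: str,
    plants: list[tuple[int, str]],
    pattern: str = E2FAT_PATTERN,
) -> str:
    """Gene-oriented window of promoter_len+1 nt ending at the TSS base.

    ``plants`` holds (tss_relative_pos, strand_of_match) for the sites to
    write in. The background is redrawn until the scanned occurrence set
    equals the planted set exactly.
    """
    want = set()
    for rel, strand in plants:
        if not -promoter_len + 2 <= rel <= -len(pattern):
            raise ValueError(f"planted position {rel} outside usable window")
        idx = rel + promoter_len  # rel = idx - promoter_len for idx < promoter_len
        want.add((idx, strand))
    for _ in range(_MAX_PROMOTER_RETRIES):
        background = _random_dna(rng, promoter_len)
        window = list(background + tss_base)
        for idx, strand in want:
            site = pattern if strand == "+" else revcomp(pattern)
            window[idx : idx + len(site)] = site
        window = "".join(window)
        if _scan_both(window, pattern) == want:
            return window
    raise RuntimeError("could not generate a clean promoter window")


def _partition_exons(start: int, end: int, n_exons: int) -> list[tuple[int, int]]:
    """Split [start, end] into n_exons exons with >= 20 nt introns."""
    length = end - start + 1
    min_needed = n_exons * 30 + (n_exons - 1) * 20
    while n_exons > 1 and length < min_needed:
        n_exons -= 1
        min_needed = n_exons * 30 + (n_exons - 1) * 20
    if n_exons <= 1:
        return [(start, end)]
    # equal exon blocks separated by fixed 20 nt introns
    exons = []
    exon_total = length - (n_exons - 1) * 20
    base_len = exon_total // n_exons
    pos = start
    for i in range(n_exons):
        elen = base_len if i < n_exons - 1 else exon_total - base_len * (n_exons - 1)
        exons.append((pos, pos + elen - 1))
        pos += elen + 20
    return exons


def make_genome(config: SynthConfig, rng: np.random.Generator | None = None):
    """Generate (genome dict, gff lines, truth skeleton, layout).

    Genes alternate strands across chromosomes, each with at least
    promoter_len+1 clean bases upstream, and exactly
    ``config.n_planted_e2fat`` binding-site occurrences across promoter
    windows (window overlap is impossible by layout).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    P = config.promoter_len
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    tf_ids = gene_ids[: config.n_tf]
    target_ids = gene_ids[config.n_tf : config.n_tf + config.n_targets]

    # --- decide motif plants -------------------------------------------------
    motif_pool = target_ids or [g for g in gene_ids if g not in tf_ids] or gene_ids
    plants_per_gene: dict[str, list[tuple[int, str]]] = {g: [] for g in gene_ids}
    planted_hits: list[tuple[str, int, str]] = []
    if config.n_planted_e2fat and motif_pool:
        carriers = list(motif_pool[: min(len(motif_pool), config.n_planted_e2fat)])
        assignments = list(carriers)
        for _ in range(config.n_planted_e2fat - len(carriers)):
            assignments.append(carriers[int(rng.integers(0, len(carriers)))])
        for gene in assignments:
            existing = {rel for rel, _ in plants_per_gene[gene]}
            for _ in range(200):
                rel = int(rng.integers(-(P - 20), -len(E2FAT_PATTERN)))
                if all(abs(rel - r) >= 15 for r in existing):
                    break
            else:
                raise RuntimeError("could not place planted motif")
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            plants_per_gene[gene].append((rel, strand))
            existing.add(rel)
    # --- lay out chromosomes -------------------------------------------------
    gap_min = 2 * P + 200  # promoter windows can never overlap
    chrom_parts: dict[str, list[str]] = {
        f"chr{c + 1}": [] for c in range(max(config.n_chroms, 1))
    }
    chrom_cursor = {c: 0 for c in chrom_parts}
    gff = ["##gff-version 3"]
    models_meta = []
    for i, gene in enumerate(gene_ids):
        chrom = f"chr{(i % max(config.n_chroms, 1)) + 1}"
        strand = "+" if (i // max(config.n_chroms, 1)) % 2 == 0 else "-"
        body_len = int(rng.integers(600, 1800))
        n_exons = int(rng.integers(1, 7))
        gap = gap_min + int(rng.integers(0, 200))
        body = _random_dna(rng, body_len)  # gene-oriented
        window = _build_promoter_window(rng, P, body[0], plants_per_gene[gene])
        parts = chrom_parts[chrom]
        cursor = chrom_cursor[chrom]
        if strand == "+":
            filler = gap - P
            parts.append(_random_dna(rng, filler))
            parts.append(window[:P])  # upstream promoter background
            start = cursor + filler + P + 1
            parts.append(body)
            end = start + body_len - 1
            tss = start
            chrom_cursor[chrom] = end
        else:
            parts.append(_random_dna(rng, gap))
            start = cursor + gap + 1
            parts.append(revcomp(body))
            end = start + body_len - 1
            parts.append(revcomp(window[:P]))  # downstream in genomic coords
            tss = end
            chrom_cursor[chrom] = end + P
        exons = _partition_exons(start, end, n_exons)
        models_meta.append((gene, chrom, strand, start, end, tss, exons))
        for rel, mstrand in sorted(plants_per_gene[gene]):
            planted_hits.append((gene, rel, mstrand))
    for chrom in chrom_parts:
        chrom_parts[chrom].append(_random_dna(rng, P + 200))
    genome = {c: "".join(parts) for c, parts in sorted(chrom_parts.items())}
    for gene, chrom, strand, start, end, tss, exons in models_meta:
        gff.append(
            f"{chrom}\tsynth\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene}"
        )
        gff.append(
            f"{chrom}\tsynth\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
            f"ID={gene}.t1;Parent={gene}"
        )
        for k, (a, b) in enumerate(exons):
            gff.append(
                f"{chrom}\tsynth\texon\t{a}\t{b}\t.\t{strand}\t.\t"
                f"ID={gene}.t1.exon{k + 1};Parent={gene}.t1"
            )
            gff.append(
                f"{chrom}\tsynth\tCDS\t{a}\t{b}\t.\t{strand}\t0\t"
                f"ID={gene}.t1.cds{k + 1};Parent={gene}.t1"
            )
    truth = GroundTruth(
        planted_motif_hits=sorted(planted_hits),
        tf_ids=tf_ids,
        target_ids=list(motif_pool[: min(len(motif_pool), config.n_planted_e2fat)])
        if config.n_planted_e2fat
        else [],
    )
    return genome, gff, truth


# --------------------------------------------------------------------------
# paralog evolution
# --------------------------------------------------------------------------

_NON_STOP_CODONS = sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random CDS of n_codons with no internal stops."""
    idx = rng.integers(0, len(_NON_STOP_CODONS), size=n_codons)
    return "".join(_NON_STOP_CODONS[i] for i in idx)


def _codon_substitutions(codon: str):
    """All (pos, base, kind) single-base changes avoiding stops."""
    aa = GENETIC_CODE[codon]
    subs = []
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            kind = "syn" if GENETIC_CODE[mutant] == aa else "nonsyn"
            subs.append((pos, base, kind))
    return subs


def _proportion_for(target_rate: float) -> float:
    """Invert the Jukes-Cantor correction: p such that JC(p) = target."""
    return 0.75 * (1.0 - math.exp(-4.0 * target_rate / 3.0))


def evolve_paralogs(
    base_cds: str,
    ds_target: float,
    dn_target: float,
    rng: np.random.Generator | int,
):
    """Derive a paralog pair whose NG86 Ks/Ka approximate the targets.

    Single-base substitutions are applied to a copy of ``base_cds``, at
    most one per codon (so difference classification is unambiguous),
    never creating a stop codon. Returns (cds_a, cds_b, substitutions)
    where each substitution is (codon_index, position, new_base, kind).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    base_cds = base_cds.upper()
    if len(base_cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    codons = [base_cds[i : i + 3] for i in range(0, len(base_cds), 3)]
    if any(c in STOP_CODONS for c in codons):
        raise ValueError("internal stop codon in base CDS")
    S = sum(codon_sites(c)[0] for c in codons)
    N = sum(codon_sites(c)[1] for c in codons)
    n_syn = int(round(_proportion_for(ds_target) * S))
    n_nonsyn = int(round(_proportion_for(dn_target) * N))
    if n_syn + n_nonsyn > len(codons):
        raise ValueError("divergence targets unreachable for this CDS length")
    syn_candidates = [
        i for i, c in enumerate(codons)
        if any(k == "syn" for _, _, k in _codon_substitutions(c))
    ]
    if len(syn_candidates) < n_syn:
        raise ValueError("not enough synonymous-capable codons for ds_target")
    chosen_syn = (
        sorted(rng.choice(syn_candidates, size=n_syn, replace=False).tolist())
        if n_syn
        else []
    )
    remaining = [i for i in range(len(codons)) if i not in set(chosen_syn)]
    nonsyn_candidates = [
        i for i in remaining
        if any(k == "nonsyn" for _, _, k in _codon_substitutions(codons[i]))
    ]
    if len(nonsyn_candidates) < n_nonsyn:
        raise ValueError("not enough nonsynonymous-capable codons for dn_target")
    chosen_nonsyn = (
        sorted(rng.choice(nonsyn_candidates, size=n_nonsyn, replace=False).tolist())
        if n_nonsyn
        else []
    )
    mutated = list(codons)
    substitutions = []
    for idx, kind in [(i, "syn") for i in chosen_syn] + [
        (i, "nonsyn") for i in chosen_nonsyn
    ]:
        options = [s for s in _codon_substitutions(codons[idx]) if s[2] == kind]
        pos, base, _ = options[int(rng.integers(0, len(options)))]
        mutated[idx] = mutated[idx][:pos] + base + mutated[idx][pos + 1 :]
        substitutions.append((idx, pos, base, kind))
    return base_cds, "".join(mutated), sorted(substitutions)


def make_paralogs(config: SynthConfig, rng: np.random.Generator, truth: GroundTruth):
    """CDS FASTA dict + pair list evolved to the configured Ks targets."""
    cds: dict[str, str] = {}
    pairs: list[tuple[str, str]] = []
    for i, ds in enumerate(config.paralog_ds_targets):
        base = random_cds(300, rng)
        a, b, _ = evolve_paralogs(base, ds, ds / 4.0, rng)
        id_a, id_b = f"par{i}a", f"par{i}b"
        cds[id_a], cds[id_b] = a, b
        pairs.append((id_a, id_b))
        truth.planted_ds[f"par{i}"] = ds
    return cds, pairs


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------

def _base_profile(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.lognormal(mean=2.0, sigma=1.0, size=n)


def _pcc(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = math.sqrt(float(np.dot(xc, xc)) * float(np.dot(yc, yc)))
    return float(np.dot(xc, yc) / denom) if denom else 0.0


def _independent_profile(
    rng: np.random.Generator, n: int, anchors: list[np.ndarray]
) -> np.ndarray:
    """Profile whose |r| vs every anchor stays below the cap."""
    for _ in range(_MAX_PROFILE_RETRIES):
        p = _base_profile(rng, n)
        if np.ptp(p) > 0 and all(abs(_pcc(p, a)) <= _PROFILE_R_CAP for a in anchors):
            return p
    raise RuntimeError("could not draw an independent expression profile")


def make_expression(
    config: SynthConfig,
    truth: GroundTruth,
    rng: np.random.Generator,
    all_gene_ids: list[str],
):
    """Expression matrix with planted regulator->target correlations.

    True-edge targets follow +/- their regulator's profile plus Gaussian
    noise of sd = noise_sd * sd(profile); everything else (other TFs,
    decoy motif carriers, background genes) is rejection-sampled to stay
    below |r| = 0.8 against every regulator at noise 0. Profiles are
    shifted, never clipped, to stay non-negative (shifts preserve r).
    """
    if config.n_conditions < 3:
        raise ValueError("need at least 3 conditions")
    n = config.n_conditions
    conditions = (
        list(DEFAULT_CONDITIONS)
        if n == len(DEFAULT_CONDITIONS)
        else [f"C{i + 1}" for i in range(n)]
    )
    tf_profiles: dict[str, np.ndarray] = {}
    anchors: list[np.ndarray] = []
    for tf in truth.tf_ids:
        p = _independent_profile(rng, n, anchors)
        tf_profiles[tf] = p
        anchors.append(p)
    edge_targets = truth.target_ids[: config.n_true_edges]
    truth.true_edges = []
    profiles: dict[str, np.ndarray] = dict(tf_profiles)
    for j, target in enumerate(edge_targets):
        reg = truth.tf_ids[j % len(truth.tf_ids)]
        sign = "activation" if j % 2 == 0 else "repression"
        base = tf_profiles[reg]
        core = base.copy() if sign == "activation" else (base.max() + 1.0 - base)
        noise = rng.normal(0.0, config.noise_sd * float(core.std()), size=n)
        prof = core + noise
        if prof.min() < 0:
            prof = prof - prof.min()
        profiles[target] = prof
        truth.true_edges.append((reg, target, sign))
    for gene in all_gene_ids:
        if gene not in profiles:
            profiles[gene] = _independent_profile(rng, n, anchors)
    values = np.round(
        np.array([profiles[g] for g in all_gene_ids]), 6
    )
    df = pd.DataFrame(values, index=all_gene_ids, columns=conditions)
    df.index.name = "gene"
    truth.tissue_max = {
        g: conditions[int(np.argmax(values[i]))] for i, g in enumerate(all_gene_ids)
    }
    return df


# --------------------------------------------------------------------------
# GO annotation and domains
# --------------------------------------------------------------------------

ENRICHED_TERM = "GO:1000000"
_BACKGROUND_TERMS = [f"GO:20000{i:02d}" for i in range(20)]


def make_go_annotation(
    config: SynthConfig,
    truth: GroundTruth,
    rng: np.random.Generator,
    all_gene_ids: list[str],
    enriched_fraction: float = 0.8,
    background_rate: float = 0.05,
) -> list[tuple[str, str]]:
    """(gene, term) rows with one term planted far above background rate."""
    truth.enriched_term = ENRICHED_TERM
    rows: list[tuple[str, str]] = []
    target_set = set(truth.target_ids)
    for gene in all_gene_ids:
        n_terms = int(rng.integers(1, 4))
        picks = rng.choice(len(_BACKGROUND_TERMS), size=n_terms, replace=False)
        for t in sorted(picks.tolist()):
            rows.append((gene, _BACKGROUND_TERMS[t]))
        threshold = enriched_fraction if gene in target_set else background_rate
        if rng.random() < threshold:
            rows.append((gene, ENRICHED_TERM))
    return rows


_TF_ARCHITECTURES = {
    "E2F": [("E2F_TD", 10, 90), ("E2F_DD", 100, 160), ("MarkedBox", 170, 210),
            ("RBR_binding", 220, 260)],
    "DP": [("DP", 30, 120), ("E2F_DD", 130, 190)],
    "DEL": [("E2F_TD", 10, 90), ("E2F_TD", 120, 200)],
}


def make_domains(truth: GroundTruth) -> list[tuple[str, str, int, int, float]]:
    """Domain-annotation rows planting an E2F/DP/DEL architecture per TF."""
    rows = []
    groups = ["E2F", "DP", "DEL"]
    for i, tf in enumerate(truth.tf_ids):
        group = groups[i % 3]
        truth.tf_groups[tf] = group
        for name, start, end in _TF_ARCHITECTURES[group]:
            rows.append((tf, name, start, end, 1e-30))
    return rows


def make_ct_table() -> list[tuple[str, str, float, float, float]]:
    """Tiny deterministic Ct table: fold 0.5 for gA, 2.0 for gB vs control."""
    return [
        ("control", "REF", 20.0, 20.0, 20.0),
        ("control", "gA", 24.0, 24.0, 24.0),
        ("control", "gB", 24.0, 24.0, 24.0),
        ("treated", "REF", 20.0, 20.0, 20.0),
        ("treated", "gA", 25.0, 25.0, 25.0),
        ("treated", "gB", 23.0, 23.0, 23.0),
    ]


# --------------------------------------------------------------------------
# top-level emitter
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate(config: SynthConfig, outdir) -> tuple[dict[str, Path], GroundTruth]:
    """Emit the full synthetic dataset to ``outdir``.

    Writes genome.fa, genes.gff3, expression.tsv, cds.fa, pairs.tsv,
    go_map.tsv, domains.tsv, ct_table.tsv, ground_truth.json and a
    manifest.json listing every emitted file with its sha256. Byte
    identical across runs with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome, gff, truth = make_genome(config, rng)
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    expr = make_expression(config, truth, rng, gene_ids)
    cds, pairs = make_paralogs(config, rng, truth)
    go_rows = make_go_annotation(config, truth, rng, gene_ids)
    domain_rows = make_domains(truth)
    ct_rows = make_ct_table()

    paths = {name: outdir / fname for name, fname in [
        ("genome", "genome.fa"), ("gff", "genes.gff3"),
        ("expression", "expression.tsv"), ("cds", "cds.fa"),
        ("pairs", "pairs.tsv"), ("go_map", "go_map.tsv"),
        ("domains", "domains.tsv"), ("ct_table", "ct_table.tsv"),
        ("ground_truth", "ground_truth.json"),
    ]}
    write_fasta(genome, paths["genome"])
    paths["gff"].write_text("\n".join(gff) + "\n")
    expr.to_csv(paths["expression"], sep="\t")
    write_fasta(cds, paths["cds"])
    with open(paths["pairs"], "w") as fh:
        fh.write("id_a\tid_b\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")
    with open(paths["go_map"], "w") as fh:
        fh.write("gene\tterm\n")
        for gene, term in go_rows:
            fh.write(f"{gene}\t{term}\n")
    with open(paths["domains"], "w") as fh:
        fh.write("protein_id\tdomain_name\tstart\tend\tevalue\n")
        for pid, name, start, end, ev in domain_rows:
            fh.write(f"{pid}\t{name}\t{start}\t{end}\t{ev:g}\n")
    with open(paths["ct_table"], "w") as fh:
        fh.write("sample\tgene\tct1\tct2\tct3\n")
        for sample, gene, c1, c2, c3 in ct_rows:
            fh.write(f"{sample}\t{gene}\t{c1:g}\t{c2:g}\t{c3:g}\n")
    truth.to_json(paths["ground_truth"])
    manifest = {p.name: _sha256(p) for p in sorted(paths.values())}
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = manifest_path
    return paths, truth
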