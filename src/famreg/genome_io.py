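"""Readers/writers for the standard formats the pipeline touches.

Coordinate convention: GFF3 1-based inclusive everywhere; conversion to
Python slices happens only inside sequence extraction code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
import networkx as nx
import pandas as pd
from Bio import SeqIO

IUPAC_BASES = set("ACGTRYSWKMBDHVN")

#: IUPAC nucleotide code -> set of concrete bases it stands for.
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: the coordinate backbone for promoter extraction.

    All intervals are 1-based inclusive genomic coordinates. ``tss`` is the
    annotated 5' end of the transcript: gene-span start on the + strand,
    gene-span end on the - strand.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_span: tuple[int, int]
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        s, e = self.gene_span
        if s > e:
            raise ValueError(f"{self.gene_id}: inverted gene span")
        expected_tss = s if self.strand == "+" else e
        if self.tss != expected_tss:
            raise ValueError(
                f"{self.gene_id}: tss {self.tss} does not match "
                f"{self.strand}-strand 5' end {expected_tss}"
            )
        prev_end = 0
        for (a, b) in self.exons:
            if a > b:
                raise ValueError(f"{self.gene_id}: inverted exon {a}-{b}")
            if a <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = b

    @property
    def n_introns(self) -> int:
        return max(len(self.exons) - 1, 0)


@dataclass(frozen=True)
class DomainAnnotation:
    """A single domain hit on a protein (1-based residue interval)."""

    protein_id: str
    domain_name: str
    start: int
    end: int
    evalue: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.protein_id}: start > end for domain hit")
        if self.evalue < 0:
            raise ValueError(f"{self.protein_id}: negative e-value")


@dataclass
class ExpressionMatrix:
    """Genes x conditions FPKM matrix backed by a pandas DataFrame."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise FormatError("duplicate gene ids in expression matrix")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate condition ids in expression matrix")
        if self.data.isna().any().any():
            raise FormatError("missing cells in expression matrix")
        if (self.data.values < 0).any():
            raise FormatError("negative FPKM values in expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.data.columns)

    def profile(self, gene_id: str):
        return self.data.loc[gene_id].to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        try:
            df = df.astype(float)
        except ValueError as exc:
            raise FormatError(f"non-numeric expression value: {exc}") from exc
        return cls(df)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t")


def read_genome(fasta_path) -> dict[str, str]:
    """Read a genome FASTA into {chrom: uppercase sequence}.

    Raises :class:`FormatError` on duplicate record ids or non-IUPAC
    characters.
    """
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"duplicate FASTA record id: {rec.id}")
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_BASES
        if bad:
            raise FormatError(
                f"non-IUPAC characters in {rec.id}: {sorted(bad)}"
            )
        genome[rec.id] = seq
    return genome


def read_fasta(path) -> dict[str, str]:
    """Read any FASTA (CDS, proteins) into {id: uppercase sequence}."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA record id: {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3(gff_path) -> list[GeneModel]:
    """Parse gene models out of a GFF3 file.

    One :class:`GeneModel` per ``gene`` feature; exon/CDS intervals come
    from the children of its first mRNA (or of the gene itself when no
    mRNA feature is present). Child features outside the parent span and
    missing strands are format errors.
    """
    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in {"+", "-"}:
            raise FormatError(f"{gene.id}: missing or invalid strand")
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parent = mrnas[0] if mrnas else gene
        exons = sorted(
            (f.start, f.end) for f in db.children(parent, featuretype="exon")
        )
        cds = sorted(
            (f.start, f.end) for f in db.children(parent, featuretype="CDS")
        )
        for a, b in exons + cds:
            if a < gene.start or b > gene.end:
                raise FormatError(
                    f"{gene.id}: child feature [{a},{b}] outside gene span"
                )
        if not exons:
            exons = [(gene.start, gene.end)]
        tss = gene.start if gene.strand == "+" else gene.end
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                tss=tss,
                gene_span=(gene.start, gene.end),
                exons=tuple(exons),
                cds=tuple(cds),
            )
        )
    return models


def read_domain_table(path) -> list[DomainAnnotation]:
    """Read a domain-annotation TSV: protein_id, domain_name, start, end, evalue."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "domain_name", "start", "end", "evalue"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"domain table missing columns: {sorted(missing)}")
    return [
        DomainAnnotation(
            protein_id=str(r.protein_id),
            domain_name=str(r.domain_name),
            start=int(r.start),
            end=int(r.end),
            evalue=float(r.evalue),
        )
        for r in df.itertuples()
    ]


def read_pair_list(path) -> list[tuple[str, str]]:
    """Read a paralog-pair TSV with columns id_a, id_b."""
    df = pd.read_csv(path, sep="\t")
    if not {"id_a", "id_b"} <= set(df.columns):
        raise FormatError("pair list must have columns id_a, id_b")
    return [(str(r.id_a), str(r.id_b)) for r in df.itertuples()]


def read_go_map(path) -> dict[str, set[str]]:
    """Read a gene->GO-term TSV (columns gene, term) into {gene: {terms}}."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "term"} <= set(df.columns):
        raise FormatError("GO map must have columns gene, term")
    mapping: dict[str, set[str]] = {}
    for r in df.itertuples():
        mapping.setdefault(str(r.gene), set()).add(str(r.term))
    return mapping


NETWORK_FORMATS = ("tsv", "graphml")


def write_network(network: nx.DiGraph, path, fmt: str = "tsv") -> None:
    """Export a regulatory network as an edge-list TSV or GraphML.

    The TSV has columns regulator, target, r, sign; a round-trip read of
    it reproduces the edge set exactly.
    """
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format: {fmt!r}")
    if fmt == "graphml":
        nx.write_graphml(network, path)
        return
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tr\tsign\n")
        for u, v, d in sorted(network.edges(data=True)):
            fh.write(
                f"{u}\t{v}\t{d.get('r', float('nan')):.6f}\t{d.get('sign', '')}\n"
            )


def read_network_tsv(path) -> nx.DiGraph:
    """Read back an edge-list TSV written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t")
    g = nx.DiGraph()
    for r in df.itertuples():
        g.add_edge(str(r.regulator), str(r.target), r=float(r.r), sign=str(r.sign))
    return g
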