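# famreg

Reusable pipeline for plant transcription-factor gene-family analysis:

* **family_classify** — E2F / DP / DEL / partial group assignment from
  domain-architecture rules, intron statistics, tandem-duplication screen.
* **promoter_cre** — strand-aware promoter extraction (−2000..+1 window,
  TSS base included), exact binding-site (TTTCCCGCC) scanning on both
  strands, and counting against a configurable IUPAC cis-element
  dictionary (elements with genome-wide totals ≤ 5 are filtered).
* **evolution** — Nei–Gojobori (1986) Ka/Ks with pathway averaging and
  Jukes–Cantor correction, plus molecular-clock dating T = Ks/2λ
  (monocot λ = 6.5×10⁻⁹, dicot λ = 1.5×10⁻⁸).
* **regnet** — coexpression network where an edge requires the binding
  site in the target promoter **and** |Pearson r| ≥ 0.90 (inclusive,
  configurable), with sign labels, hub ranking and tissue-of-maximum
  node annotation.
* **enrichment** — hypergeometric upper-tail GO over-representation with
  Benjamini–Hochberg FDR.
* **expression_qpcr** — 2^−ΔΔCt relative expression and log2(FPKM+1)
  heatmap transforms.
* **synthetic_data** — seeded generator producing a toy genome (FASTA +
  GFF3), planted promoter binding sites on both strands, paralog pairs
  evolved to target Ks values, a 13-condition expression matrix with
  planted regulator→target correlations, and a GO map with one planted
  enriched term — all with exact ground truth for recovery testing.
* **genome_io / cli** — FASTA/GFF3/TSV/GraphML IO and a click-based
  pipeline with hashed output manifests.

## CLI

```sh
# self-contained synthetic demo: generates data, runs every stage,
# scores recovery against the planted ground truth
famreg demo --seed 42 --outdir out/demo

# full pipeline on explicit inputs
famreg run --genome genome.fa --gff genes.gff3 --domains domains.tsv \
    --expression expr.tsv --cds cds.fa --pairs pairs.tsv \
    --go-map go.tsv --outdir out/run

# individual stages
famreg scan --genome genome.fa --gff genes.gff3 --outdir out/scan
famreg kaks --cds cds.fa --pairs pairs.tsv --outdir out/kaks --lambda monocot
famreg qpcr --ct-table ct.tsv --reference-gene REF --calibrator control \
    --out folds.tsv
```

Every run writes a `manifest.json` of sha256 hashes; identical seeds give
byte-identical outputs.

## Input formats

Genome FASTA; GFF3 gene models (gene/mRNA/exon/CDS, 1-based inclusive);
expression TSV (genes × conditions, FPKM); domain table TSV
(`protein_id, domain_name, start, end, evalue`); CDS FASTA plus pair-list
TSV (`id_a, id_b`); GO map TSV (`gene, term`); Ct table TSV
(`sample, gene, ct1..ctN`). Networks export as edge-list TSV and GraphML.
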