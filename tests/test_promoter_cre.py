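import pytest
from hypothesis import given, strategies as st

from famreg.genome_io import GeneModel, revcomp
from famreg.promoter_cre import (
    CreEntry,
    DEFAULT_CRE_DICTIONARY,
    PromoterRegion,
    count_cres,
    extract_promoter,
    find_target_genes,
    scan_motif,
)

MOTIF = "TTTCCCGCC"


def gene(gene_id, strand, start, end, chrom="c1"):
    return GeneModel(gene_id, chrom, strand,
                     tss=start if strand == "+" else end,
                     gene_span=(start, end), exons=((start, end),))


def promoter(seq, gene_id="g", strand="+"):
    return PromoterRegion(gene_id, seq, (1, len(seq)), strand)


class TestExtractPromoter:
    def test_plus_strand_window(self):
        genome = {"c1": "A" * 10_000}
        prom = extract_promoter(genome, gene("g", "+", 5000, 6000))
        assert prom.genomic_interval == (3000, 5000)
        assert len(prom.seq) == 2001
        assert not prom.truncated

    def test_minus_strand_window_revcomped(self):
        seq = "".join("ACGT"[(i // 7) % 4] for i in range(10_000))
        genome = {"c1": seq}
        prom = extract_promoter(genome, gene("g", "-", 4000, 5000))
        assert prom.genomic_interval == (5000, 7000)
        assert prom.seq == revcomp(seq[4999:7000])

    def test_truncated_at_contig_start(self):
        genome = {"c1": "A" * 10_000}
        prom = extract_promoter(genome, gene("g", "+", 1500, 2500))
        assert prom.genomic_interval == (1, 1500)
        assert prom.truncated

    def test_tss_outside_chromosome_rejected(self):
        genome = {"c1": "A" * 100}
        with pytest.raises(ValueError, match="TSS"):
            extract_promoter(genome, gene("g", "+", 500, 600))

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(KeyError):
            extract_promoter({"c1": "A" * 100}, gene("g", "+", 10, 20, chrom="c9"))

    def test_tss_relative_coordinates(self):
        genome = {"c1": "A" * 10_000}
        prom = extract_promoter(genome, gene("g", "+", 5000, 6000))
        assert prom.tss_relative(0) == -2000
        assert prom.tss_relative(2000) == 1  # TSS base, no position 0
        assert prom.tss_relative(1999) == -1


class TestScanMotif:
    def test_direct_match(self):
        hits = scan_motif(promoter("AAA" + MOTIF + "AAA"), "E2FAT", MOTIF)
        assert len(hits) == 1
        assert hits[0].strand_of_match == "+"
        assert hits[0].matched_seq == MOTIF

    def test_reverse_complement_match(self):
        hits = scan_motif(promoter("AAA" + "GGCGGGAAA" + "AAA"), "E2FAT", MOTIF)
        assert len(hits) == 1
        assert hits[0].strand_of_match == "-"

    def test_no_match(self):
        assert scan_motif(promoter("A" * 50), "E2FAT", MOTIF) == []

    def test_overlapping_matches_all_reported(self):
        hits = scan_motif(promoter("ATATATATA"), "AT", "ATA")
        assert len([h for h in hits if h.strand_of_match == "+"]) == 4

    def test_n_in_sequence_never_matches(self):
        seq = "AAA" + MOTIF.replace("C", "N", 1) + "AAA"
        assert scan_motif(promoter(seq), "E2FAT", MOTIF) == []

    def test_iupac_pattern_expansion(self):
        hits = scan_motif(promoter("CAGGTG"), "MYC", "CANNTG")
        assert len(hits) == 1

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            scan_motif(promoter("ACGT"), "x", "")

    def test_single_strand_mode(self):
        hits = scan_motif(promoter("GGCGGGAAA"), "E2FAT", MOTIF, both_strands=False)
        assert hits == []

    @given(st.text(alphabet="ACGT", min_size=20, max_size=80),
           st.sampled_from([MOTIF, "TGACG", "ACGTGGC"]))
    def test_strand_symmetry(self, seq, pattern):
        """Scanning seq for P equals scanning revcomp(seq) for P with the
        match strands swapped."""
        fwd = scan_motif(promoter(seq), "m", pattern)
        rev = scan_motif(promoter(revcomp(seq)), "m", pattern)
        assert len(fwd) == len(rev)
        swap = {"+": "-", "-": "+"}
        assert sorted(swap[h.strand_of_match] for h in fwd) == sorted(
            h.strand_of_match for h in rev
        )


class TestStrandInvariance:
    def test_same_relative_position_both_strands(self):
        """A site planted at the same TSS-relative spot is found identically
        whether the gene sits on + or - strand."""
        pad = "A" * 1991
        window = pad + MOTIF + "G"  # site starts at -9, TSS base last
        chrom_plus = "T" * 500 + window + "C" * 3000
        tss_plus = 500 + len(window)
        g_plus = gene("gp", "+", tss_plus, tss_plus + 100)
        chrom_minus = "C" * 3000 + revcomp(window) + "T" * 500
        tss_minus = 3001
        g_minus = gene("gm", "-", tss_minus - 100, tss_minus)
        hits_p = scan_motif(
            extract_promoter({"c1": chrom_plus}, g_plus), "E2FAT", MOTIF
        )
        hits_m = scan_motif(
            extract_promoter({"c1": chrom_minus}, g_minus), "E2FAT", MOTIF
        )
        assert [(h.tss_relative_start, h.strand_of_match) for h in hits_p] == [
            (h.tss_relative_start, h.strand_of_match) for h in hits_m
        ] == [(-9, "+")]


class TestFindTargetGenes:
    def test_planted_genes_recovered(self, small_dataset):
        from famreg.genome_io import read_genome, read_gff3

        _, paths, truth = small_dataset
        genome = read_genome(paths["genome"])
        promoters = [
            extract_promoter(genome, m) for m in read_gff3(paths["gff"])
        ]
        targets = find_target_genes(promoters)
        assert targets == sorted({g for g, _, _ in truth.planted_motif_hits})

    def test_zero_planted_empty(self):
        proms = [promoter("A" * 100, gene_id=f"g{i}") for i in range(5)]
        assert find_target_genes(proms) == []

    def test_gene_with_two_hits_counted_once(self):
        seq = MOTIF + "AAAA" + MOTIF
        assert find_target_genes([promoter(seq, gene_id="g1")]) == ["g1"]


class TestCountCres:
    def test_two_sites_counted(self):
        entry = (CreEntry("ABRE", "ACGTGGC", "hormone"),)
        prom = promoter("ACGTGGC" + "T" * 10 + "ACGTGGC", gene_id="g1")
        raw, _ = count_cres([prom], entry, min_total=0)
        assert raw["ABRE"]["g1"] == 2

    def test_min_total_boundary_excludes_equal(self):
        entry = (CreEntry("X", "ACGTACGTT", "other"),)
        proms = [promoter("ACGTACGTT", gene_id=f"g{i}") for i in range(5)]
        raw, filtered = count_cres(proms, entry, min_total=5)
        assert sum(raw["X"].values()) == 5
        assert "X" not in filtered  # needs strictly more than five

    def test_above_threshold_retained(self):
        entry = (CreEntry("X", "ACGTACGTT", "other"),)
        proms = [promoter("ACGTACGTT", gene_id=f"g{i}") for i in range(6)]
        _, filtered = count_cres(proms, entry, min_total=5)
        assert "X" in filtered

    def test_empty_dictionary_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            count_cres([promoter("ACGT")], (), min_total=5)

    def test_default_dictionary_entries(self):
        ids = {e.motif_id for e in DEFAULT_CRE_DICTIONARY}
        assert {"ABRE", "TGACG-motif", "TCA-element", "CAT-box", "P-box",
                "GARE-motif", "MYB", "MYC", "E2FAT"} <= ids
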