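"""Generator self-consistency: planted truth must be recoverable by
independent oracles that only look at the emitted files."""

import re

import numpy as np
import pytest

from famreg.evolution import STOP_CODONS, kaks, pair_codon_alignment
from famreg.synthetic_data import (
    SynthConfig,
    evolve_paralogs,
    generate,
    make_expression,
    make_genome,
    random_cds,
)

MOTIF = "TTTCCCGCC"


# -- independent promoter oracle: plain-text parsing + regex only ------------

def _parse_fasta(path):
    seqs, name = {}, None
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = []
        else:
            seqs[name].append(line.strip())
    return {k: "".join(v) for k, v in seqs.items()}


def _rc(seq):
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _oracle_promoter_hits(genome_path, gff_path, promoter_len=2000):
    """Regex scan of every promoter window, both strands, from raw files."""
    genome = _parse_fasta(genome_path)
    hits = []
    for line in gff_path.read_text().splitlines():
        if line.startswith("#"):
            continue
        chrom, _, ftype, start, end, _, strand, _, attrs = line.split("\t")
        if ftype != "gene":
            continue
        gene = dict(kv.split("=") for kv in attrs.split(";"))["ID"]
        start, end = int(start), int(end)
        if strand == "+":
            window = genome[chrom][max(0, start - 1 - promoter_len) : start]
        else:
            window = _rc(genome[chrom][end - 1 : end + promoter_len])
        L = len(window)
        for m in re.finditer(f"(?=({MOTIF}))", window):
            d = (L - 1) - m.start()
            hits.append((gene, 1 if d == 0 else -d, "+"))
        for m in re.finditer(f"(?=({_rc(MOTIF)}))", window):
            d = (L - 1) - m.start()
            hits.append((gene, 1 if d == 0 else -d, "-"))
    return sorted(hits)


class TestMakeGenome:
    def test_planted_count_matches_oracle(self, small_dataset):
        config, paths, truth = small_dataset
        oracle = _oracle_promoter_hits(paths["genome"], paths["gff"])
        assert len(oracle) == config.n_planted_e2fat == 4
        assert oracle == sorted(truth.planted_motif_hits)

    def test_zero_planted_zero_hits(self, tmp_path):
        config = SynthConfig(n_genes=6, n_planted_e2fat=0, n_tf=0,
                             n_targets=0, n_true_edges=0, seed=3)
        paths, _ = generate(config, tmp_path)
        assert _oracle_promoter_hits(paths["genome"], paths["gff"]) == []

    def test_same_seed_byte_identical(self, tmp_path):
        config = SynthConfig(n_genes=8, n_planted_e2fat=5, n_tf=2,
                             n_targets=4, n_true_edges=2, seed=11)
        p1, _ = generate(config, tmp_path / "a")
        p2, _ = generate(config, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_genes_on_both_strands(self, small_dataset):
        _, paths, _ = small_dataset
        strands = {
            line.split("\t")[6]
            for line in paths["gff"].read_text().splitlines()
            if "\tgene\t" in line
        }
        assert strands == {"+", "-"}


class TestConfigInvariants:
    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_genes=-1)

    def test_ds_target_range_enforced(self):
        with pytest.raises(ValueError):
            SynthConfig(paralog_ds_targets=(0.9,))

    def test_edge_capacity_enforced(self):
        with pytest.raises(ValueError):
            SynthConfig(n_genes=10, n_tf=1, n_targets=5,
                        n_planted_e2fat=2, n_true_edges=4)


class TestEvolveParalogs:
    def test_zero_targets_identical(self, rng):
        base = random_cds(100, rng)
        a, b, subs = evolve_paralogs(base, 0.0, 0.0, rng)
        assert a == b == base
        assert subs == []

    def test_ks_recovered_within_ten_percent(self, rng):
        base = random_cds(300, np.random.default_rng(1))
        a, b, _ = evolve_paralogs(base, 0.2, 0.05, np.random.default_rng(1))
        res = kaks(pair_codon_alignment(a, b))
        assert res.Ks == pytest.approx(0.2, rel=0.10)

    def test_no_stop_codons_created(self, rng):
        for seed in range(5):
            g = np.random.default_rng(seed)
            a, b, _ = evolve_paralogs(random_cds(200, g), 0.4, 0.1, g)
            codons = {b[i : i + 3] for i in range(0, len(b), 3)}
            assert not codons & STOP_CODONS

    def test_unreachable_target_rejected(self, rng):
        # 2 codons cannot host the substitutions a ds of 0.6 demands... use
        # a sequence with no synonymous capacity at all instead
        with pytest.raises(ValueError):
            evolve_paralogs("ATGTGG" * 30, 0.6, 0.6, rng)  # Met/Trp only

    def test_length_not_multiple_of_three_rejected(self, rng):
        with pytest.raises(ValueError, match="multiple of 3"):
            evolve_paralogs("ATGC", 0.1, 0.0, rng)


class TestMakeExpression:
    def _truth_and_matrix(self, noise_sd, seed=5):
        config = SynthConfig(n_genes=12, n_planted_e2fat=6, n_tf=2,
                             n_targets=6, n_true_edges=4,
                             noise_sd=noise_sd, seed=seed)
        rng = np.random.default_rng(seed)
        _, _, truth = make_genome(config, rng)
        genes = [f"g{i:04d}" for i in range(config.n_genes)]
        df = make_expression(config, truth, rng, genes)
        return truth, df

    def test_noise_free_edges_have_unit_correlation(self):
        truth, df = self._truth_and_matrix(0.0)
        for reg, target, sign in truth.true_edges:
            r = np.corrcoef(df.loc[reg], df.loc[target])[0, 1]
            expected = 1.0 if sign == "activation" else -1.0
            assert r == pytest.approx(expected, abs=1e-9)

    def test_decoys_below_threshold(self):
        truth, df = self._truth_and_matrix(0.0)
        edge_targets = {t for _, t, _ in truth.true_edges}
        decoys = [t for t in truth.target_ids if t not in edge_targets]
        assert decoys
        for reg in truth.tf_ids:
            for decoy in decoys:
                r = np.corrcoef(df.loc[reg], df.loc[decoy])[0, 1]
                assert abs(r) < 0.90

    def test_values_non_negative(self):
        _, df = self._truth_and_matrix(0.5)
        assert (df.values >= 0).all()

    def test_thirteen_condition_labels(self):
        _, df = self._truth_and_matrix(0.0)
        assert list(df.columns)[:3] == ["S1", "S2", "S3"]
        assert list(df.columns)[-1] == "O"


class TestMakeGoAnnotation:
    def test_planted_term_tops_enrichment(self, small_dataset):
        from famreg.enrichment import enrich
        from famreg.genome_io import read_go_map

        _, paths, truth = small_dataset
        annotation = read_go_map(paths["go_map"])
        background = set(annotation)
        targets = set(truth.target_ids) & background
        results = enrich(targets, annotation, background)
        assert results[0].term == truth.enriched_term

    def test_same_seed_identical_mapping(self, tmp_path):
        config = SynthConfig(n_genes=8, n_planted_e2fat=4, n_tf=1,
                             n_targets=4, n_true_edges=2, seed=9)
        p1, _ = generate(config, tmp_path / "x")
        p2, _ = generate(config, tmp_path / "y")
        assert p1["go_map"].read_text() == p2["go_map"].read_text()


def test_manifest_covers_all_emitted_files(small_dataset):
    import json

    _, paths, _ = small_dataset
    manifest = json.loads(paths["manifest"].read_text())
    emitted = {p.name for k, p in paths.items() if k != "manifest"}
    assert emitted == set(manifest)
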