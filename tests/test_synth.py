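import numpy as np
import pytest

from telocus.age import kimura2p
from telocus.io import read_fasta, read_gene_gff3, read_te_bed, write_fasta, write_gene_gff3, write_te_bed
from telocus.synth import (
    GenomeCapacityError,
    SynthConfig,
    build_genome,
    mutate_from_consensus,
    random_dna,
    revcomp,
    simulate_reads,
    simulate_sample,
)


class TestMutateFromConsensus:
    def test_zero_divergence_is_identity(self, rng):
        seq = random_dna(rng, 400)
        out, realized = mutate_from_consensus(seq, 0.0, seed=3)
        assert out == seq
        assert realized == 0.0

    def test_deterministic_given_seed(self, rng):
        seq = random_dna(rng, 500)
        a = mutate_from_consensus(seq, 12.0, seed=9)
        b = mutate_from_consensus(seq, 12.0, seed=9)
        assert a == b
        c = mutate_from_consensus(seq, 12.0, seed=10)
        assert c != a

    def test_realized_divergence_tracks_target(self, rng):
        # Monte-Carlo against the K2P oracle: 1 kb consensus, 100 seeds
        seq = random_dna(rng, 1000)
        errs = []
        for seed in range(100):
            out, realized = mutate_from_consensus(seq, 15.0, seed=seed)
            assert realized == pytest.approx(kimura2p(out, seq), abs=1e-12)
            errs.append(abs(realized - 15.0))
        assert np.mean(errs) < 1.5
        assert max(errs) < 1.5  # tight for >= 300 bp sequences

    def test_empty_and_out_of_range(self):
        with pytest.raises(ValueError):
            mutate_from_consensus("", 5.0, seed=1)
        with pytest.raises(ValueError):
            mutate_from_consensus("ACGT" * 100, 60.0, seed=1)


class TestBuildGenome:
    def test_te_intervals_store_inserted_sequence(self, small_build):
        # genome substring at each TE interval is the mutated copy
        # (reverse-complemented for minus-strand copies) at the stored divergence
        b = small_build
        for te in b.tes:
            sub = b.genome[te.chrom][te.start : te.end]
            copy = sub if te.strand == "+" else revcomp(sub)
            cons = b.consensi[te.consensus_id].sequence
            assert len(copy) == len(cons)
            assert kimura2p(copy, cons) == pytest.approx(te.divergence_pct, abs=1e-9)

    def test_te_copies_do_not_overlap(self, small_build):
        by_chrom = {}
        for te in small_build.tes:
            by_chrom.setdefault(te.chrom, []).append((te.start, te.end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s0, e0), (s1, _) in zip(ivs, ivs[1:]):
                assert e0 <= s1

    def test_young_fraction_matches_default_target(self):
        cfg = SynthConfig(
            n_chroms=4, chrom_length=120_000, n_genes=10, n_te=500,
            placement_fractions=(0.04, 0.08, 0.88),
            expressed_fraction=0.2, n_planted_de=0, n_coupled_pairs=0,
        )
        b = build_genome(cfg, seed=13)
        assert len(b.tes) == 500
        young = sum(1 for t in b.tes if t.divergence_pct <= 10.0) / len(b.tes)
        assert young == pytest.approx(0.161, abs=0.03)

    def test_minimal_intronic_placement(self):
        cfg = SynthConfig(
            n_chroms=1, chrom_length=30_000, n_genes=1, n_te=1,
            placement_fractions=(0.0, 1.0, 0.0),
            expressed_fraction=1.0, n_planted_de=0, n_coupled_pairs=0,
        )
        b = build_genome(cfg, seed=5)
        assert len(b.tes) == 1
        te = b.tes[0]
        assert b.truth.placement_context[te.te_id] == "Intronic"
        g = b.genes[0]
        assert g.start <= te.start and te.end <= g.end
        assert all(te.end <= es or ee <= te.start for es, ee in g.exons)

    def test_capacity_error_when_genome_is_full(self):
        cfg = SynthConfig(n_chroms=1, chrom_length=8_000, n_genes=1, n_te=100)
        with pytest.raises(GenomeCapacityError):
            build_genome(cfg, seed=2)

    def test_deterministic_outputs_byte_identical(self, tmp_path):
        cfg = SynthConfig(n_te=30, n_genes=4)
        files = []
        for d in ("a", "b"):
            b = build_genome(cfg, seed=42)
            root = tmp_path / d
            root.mkdir()
            write_fasta(b.genome, root / "g.fa")
            write_te_bed(b.tes, root / "t.bed")
            write_gene_gff3(b.genes, root / "g.gff3")
            files.append(root)
        for name in ("g.fa", "t.bed", "g.gff3"):
            assert (files[0] / name).read_bytes() == (files[1] / name).read_bytes()

    def test_annotation_round_trips_through_files(self, small_build, tmp_path):
        write_fasta(small_build.genome, tmp_path / "g.fa")
        write_te_bed(small_build.tes, tmp_path / "t.bed")
        write_gene_gff3(small_build.genes, tmp_path / "g.gff3")
        genome = read_fasta(tmp_path / "g.fa")
        assert genome == small_build.genome
        tes = read_te_bed(tmp_path / "t.bed")
        assert [(t.te_id, t.chrom, t.start, t.end, t.strand) for t in tes] == [
            (t.te_id, t.chrom, t.start, t.end, t.strand) for t in small_build.tes
        ]
        genes = read_gene_gff3(tmp_path / "g.gff3")
        assert {g.gene_id: g.exons for g in genes} == {
            g.gene_id: g.exons for g in small_build.genes
        }


class TestSimulateReads:
    def test_error_free_reads_are_genome_substrings(self, small_build):
        sim = simulate_sample(small_build, small_build.truth.samples[0],
                              error_rate=0.0, seed=3)
        assert len(sim.read_pairs) > 0
        for rp in sim.read_pairs:
            chrom, fs, fe, _ = rp.true_origin
            seq = small_build.genome[chrom]
            for mate in (rp.mate1, rp.mate2):
                assert mate in seq or revcomp(mate) in seq

    def test_true_origin_overlaps_source_locus(self, small_build):
        b = small_build
        te_ivs = {t.te_id: (t.chrom, t.start, t.end) for t in b.tes}
        sim = simulate_sample(b, b.truth.samples[1], error_rate=0.0, seed=4)
        for rp in sim.read_pairs:
            chrom, fs, fe, fid = rp.true_origin
            if fid in te_ivs:
                c, s, e = te_ivs[fid]
                assert c == chrom and fs < e and fe > s

    def test_expected_pair_count_follows_coverage_formula(self):
        # one 720 bp locus at 20x with L=36 -> ~200 pairs
        cfg = SynthConfig(
            n_chroms=1, chrom_length=20_000, n_genes=1, n_te=1,
            consensus_length={"LINE": (720, 720), "SINE": (720, 720),
                              "LTR": (720, 720), "DNA": (720, 720)},
            placement_fractions=(0.0, 0.0, 1.0),
            expressed_fraction=1.0, n_planted_de=0, n_coupled_pairs=0,
            te_log2_sd=0.0,
        )
        b = build_genome(cfg, seed=8)
        assert b.tes[0].length == 720
        counts = []
        for seed in range(30):
            sim = simulate_sample(b, b.truth.samples[0], read_length=36,
                                  coverage=20, error_rate=0.0, seed=seed, te_only=True)
            counts.append(sim.te_true_counts[b.tes[0].te_id])
            assert len(sim.read_pairs) == counts[-1]
        assert np.mean(counts) == pytest.approx(200, rel=0.10)

    def test_zero_coverage_yields_no_reads(self, small_build):
        sim = simulate_sample(small_build, small_build.truth.samples[0],
                              coverage=0.0, seed=1, te_only=True)
        assert sim.read_pairs == []

    def test_short_locus_skipped_with_warning(self, small_build, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="telocus.synth"):
            sim = simulate_sample(small_build, small_build.truth.samples[0],
                                  read_length=400, seed=1, te_only=True)
        short = [t for t in small_build.tes
                 if t.te_id in small_build.truth.expressed_loci and t.length < 400]
        if short:
            assert "shorter than read length" in caplog.text
        assert all(len(rp.mate1) == 400 for rp in sim.read_pairs)

    def test_error_rate_validated(self, small_build):
        with pytest.raises(ValueError):
            simulate_sample(small_build, small_build.truth.samples[0], error_rate=0.2)

    def test_per_sample_determinism(self, small_build):
        a = simulate_reads(small_build, seed=6, samples=small_build.truth.samples[:2])
        b = simulate_reads(small_build, seed=6, samples=small_build.truth.samples[:2])
        for name in a:
            assert a[name].read_pairs == b[name].read_pairs
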