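import numpy as np
import pytest

from telocus.quant import (
    GenomeIndex,
    LocusQuant,
    align_read_pair,
    align_reads,
    align_sequence,
    em_assign,
    fragment_locus_sets,
    read_alignments_sam,
    score_locus,
)
from telocus.synth import ReadPair, TEAnnotation, random_dna, revcomp, simulate_sample


def _te(te_id, chrom, start, end, length=None):
    return TEAnnotation(
        te_id=te_id, chrom=chrom, start=start, end=end, strand="+",
        subfamily="s", family="f", te_class="SINE", consensus_id="c",
        divergence_pct=0.0,
    )


class TestAligner:
    def test_unique_exact_substring_single_hit(self, rng):
        g = {"chr1": random_dna(rng, 5000)}
        idx = GenomeIndex(g)
        read = g["chr1"][1000:1036]
        hits = align_sequence(idx, read)
        assert len(hits) == 1
        h = hits[0]
        assert (h.chrom, h.start, h.strand, h.mismatches) == ("chr1", 1000, "+", 0)

    def test_duplicated_locus_gives_two_hits(self, rng):
        core = random_dna(rng, 1000)
        g = {"chr1": random_dna(rng, 500) + core + random_dna(rng, 500)
                      + core + random_dna(rng, 500)}
        idx = GenomeIndex(g)
        read = core[100:136]
        hits = align_sequence(idx, read)
        starts = sorted(h.start for h in hits)
        assert len(hits) == 2
        assert starts == [600, 2100]

    def test_reverse_complement_reads_align(self, rng):
        g = {"chr1": random_dna(rng, 3000)}
        idx = GenomeIndex(g)
        read = revcomp(g["chr1"][700:736])
        hits = align_sequence(idx, read)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].start == 700

    def _brute_force(self, genome, read, max_mismatch):
        """Exhaustive scan of every position/strand at <= max_mismatch."""
        out = []
        for strand, q in (("+", read), ("-", revcomp(read))):
            qa = np.frombuffer(q.encode(), dtype=np.uint8)
            for chrom, seq in genome.items():
                arr = np.frombuffer(seq.encode(), dtype=np.uint8)
                for p in range(len(arr) - len(qa) + 1):
                    mm = int(np.count_nonzero(arr[p : p + len(qa)] != qa))
                    if mm <= max_mismatch:
                        out.append((chrom, p, strand, mm))
        if not out:
            return []
        best = min(mm for *_, mm in out)
        return sorted(x for x in out if x[3] == best)

    def test_matches_exhaustive_scan_oracle(self, rng):
        # genome with a duplicated block so multi-mapping occurs
        block = random_dna(rng, 300)
        g = {
            "chr1": random_dna(rng, 2000) + block + random_dna(rng, 700),
            "chr2": block + random_dna(rng, 1500),
        }
        idx = GenomeIndex(g)
        reads = []
        for _ in range(40):
            chrom = "chr1" if rng.random() < 0.6 else "chr2"
            p = int(rng.integers(0, len(g[chrom]) - 36))
            read = g[chrom][p : p + 36]
            if rng.random() < 0.5:
                read = revcomp(read)
            if rng.random() < 0.5:  # inject up to 2 errors
                arr = list(read)
                for _ in range(int(rng.integers(1, 3))):
                    arr[int(rng.integers(0, 36))] = "ACGT"[rng.integers(0, 4)]
                read = "".join(arr)
            reads.append(read)
        for read in reads:
            got = sorted((h.chrom, h.start, h.strand, h.mismatches)
                         for h in align_sequence(idx, read, max_mismatch=2))
            assert got == self._brute_force(g, read, 2)

    def test_paired_placement_spans_fragment(self, rng):
        g = {"chr1": random_dna(rng, 4000)}
        idx = GenomeIndex(g)
        frag = g["chr1"][500:622]  # 122 bp fragment
        placements = align_read_pair(idx, frag[:36], revcomp(frag[-36:]))
        assert len(placements) == 1
        pl = placements[0]
        assert (pl.chrom, pl.start, pl.end, pl.mismatches) == ("chr1", 500, 622, 0)

    def test_unpaired_reads_recorded_as_unaligned(self, rng):
        g = {"chr1": random_dna(rng, 2000)}
        idx = GenomeIndex(g)
        rp = ReadPair("r1", random_dna(rng, 36), random_dna(rng, 36), ("x", 0, 0, "x"))
        recs = align_reads([rp], idx)
        assert len(recs) == 1
        assert not recs[0].aligned


class TestEM:
    def test_all_unique_equals_raw_overlap_counts(self, rng):
        g = {"chr1": random_dna(rng, 6000)}
        idx = GenomeIndex(g)
        tes = [_te("A", "chr1", 1000, 1500), _te("B", "chr1", 3000, 3600)]
        reads = []
        for i in range(30):
            src = tes[i % 2]
            p = int(rng.integers(src.start, src.end - 122))
            frag = g["chr1"][p : p + 122]
            reads.append(ReadPair(f"r{i}", frag[:36], revcomp(frag[-36:]), ("chr1", p, p + 122, src.te_id)))
        recs = align_reads(reads, idx)
        quants = {q.te_id: q for q in em_assign(recs, tes)}
        assert quants["A"].total_count == 15
        assert quants["B"].total_count == 15
        assert quants["A"].unique_count == 15
        assert quants["A"].score == 100

    def test_two_identical_loci_split_evenly(self, rng):
        core = random_dna(rng, 800)
        g = {"chr1": random_dna(rng, 300) + core + random_dna(rng, 300)
                      + core + random_dna(rng, 300)}
        idx = GenomeIndex(g)
        tes = [_te("L1", "chr1", 300, 1100), _te("L2", "chr1", 1400, 2200)]
        reads = []
        for i in range(20):
            p = int(rng.integers(300, 1100 - 122))
            frag = g["chr1"][p : p + 122]
            reads.append(ReadPair(f"r{i}", frag[:36], revcomp(frag[-36:]), ("chr1", p, p + 122, "L1")))
        recs = align_reads(reads, idx)
        assert all(not r.is_unique for r in recs)
        quants = {q.te_id: q for q in em_assign(recs, tes)}
        assert quants["L1"].total_count == pytest.approx(10, abs=1e-6)
        assert quants["L2"].total_count == pytest.approx(10, abs=1e-6)
        assert quants["L1"].unique_count == 0
        assert quants["L1"].score == 0

    @staticmethod
    def _em_oracle(classes, lengths, tol=1e-10, max_iter=10_000):
        """Independent dense fixed-point iteration over ambiguity classes."""
        n = len(lengths)
        total = sum(classes.values())
        counts = np.full(n, total / n)
        for _ in range(max_iter):
            theta = counts / lengths
            new = np.zeros(n)
            for loci, cnt in classes.items():
                w = np.array([theta[i] for i in loci])
                if w.sum() == 0:
                    w = np.ones(len(loci))
                w = w / w.sum()
                for i, wi in zip(loci, w):
                    new[i] += cnt * wi
            if np.max(np.abs(new - counts)) < tol:
                return new
            counts = new
        return counts

    def test_three_locus_mixed_instance_matches_oracle(self):
        tes = [_te("A", "chr1", 0, 500), _te("B", "chr1", 1000, 1800),
               _te("C", "chr1", 3000, 3400)]
        lengths = np.array([500.0, 800.0, 400.0])
        classes = {(0,): 30, (1,): 10, (0, 1): 40, (1, 2): 12, (0, 1, 2): 8, (2,): 3}

        class FakeRecord:
            def __init__(self, pls):
                self.placements = pls

        # build synthetic alignment records realizing exactly these classes
        from telocus.quant import FragmentPlacement

        recs = []
        span = {0: (0, 500), 1: (1000, 1800), 2: (3000, 3400)}
        for loci, cnt in classes.items():
            for _ in range(cnt):
                pls = [FragmentPlacement("chr1", span[i][0], span[i][0] + 50, 0) for i in loci]
                recs.append(FakeRecord(pls))
        got = {q.te_id: q.total_count for q in em_assign(recs, tes, tol=1e-9)}
        want = self._em_oracle(classes, lengths)
        for i, te_id in enumerate("ABC"):
            assert got[te_id] == pytest.approx(want[i], abs=1e-6)
        assert sum(got.values()) == pytest.approx(sum(classes.values()), abs=1e-9)

    def test_empty_annotation_gives_empty_result(self):
        assert em_assign([], []) == []

    def test_conservation_on_simulated_sample(self, small_build):
        b = small_build
        sim = simulate_sample(b, b.truth.samples[0], error_rate=0.0, seed=2, te_only=True)
        idx = GenomeIndex(b.genome)
        recs = align_reads(sim.read_pairs, idx)
        quants = em_assign(recs, b.tes)
        n_te_frags = sum(fragment_locus_sets(recs, b.tes).values())
        assert sum(q.total_count for q in quants) == pytest.approx(n_te_frags, abs=1e-6)
        # every simulated fragment comes from a TE, so nothing is lost
        assert n_te_frags == len(sim.read_pairs)


class TestScore:
    @pytest.mark.parametrize(
        "unique, total, expected",
        [(4, 4, 100), (0, 10, 0), (3, 4, 75), (0, 0, 0), (1, 3, 33)],
    )
    def test_score_values(self, unique, total, expected):
        assert score_locus(LocusQuant("x", float(total), unique)) == expected

    def test_monotone_in_unique_fraction(self):
        scores = [score_locus(LocusQuant("x", 40.0, u)) for u in range(0, 41, 5)]
        assert scores == sorted(scores)

    def test_mean_score_drops_as_duplicate_divergence_vanishes(self, rng):
        # known weakness of locus-level TE scoring: the score collapses for
        # young (near-identical) copies because multi-mapping explodes
        mean_scores = []
        for div in (0.0, 1.0, 20.0):
            cons = random_dna(rng, 600)
            from telocus.synth import mutate_from_consensus

            c1, _ = mutate_from_consensus(cons, div, seed=1)
            c2, _ = mutate_from_consensus(cons, div, seed=2)
            g = {"chr1": random_dna(rng, 400) + c1 + random_dna(rng, 400) + c2 + random_dna(rng, 400)}
            idx = GenomeIndex(g)
            tes = [_te("L1", "chr1", 400, 1000), _te("L2", "chr1", 1400, 2000)]
            reads = []
            for i in range(60):
                p = int(rng.integers(400, 1000 - 122))
                frag = g["chr1"][p : p + 122]
                reads.append(ReadPair(f"r{i}", frag[:36], revcomp(frag[-36:]), ("chr1", p, p + 122, "L1")))
            quants = em_assign(align_reads(reads, idx), tes)
            present = [q for q in quants if q.total_count > 0]
            mean_scores.append(np.mean([q.score for q in present]))
        assert mean_scores[0] < mean_scores[2]
        assert mean_scores[0] <= mean_scores[1] <= mean_scores[2]
        assert mean_scores[0] == 0  # identical copies: nothing is unique
        assert mean_scores[2] == 100


class TestSamIngest:
    def test_multihit_sam_records(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\n"
            "@SQ\tSN:chr1\tLN:10000\n"
            "f1\t0\tchr1\t101\t255\t36M\t*\t0\t0\t" + "A" * 36 + "\t*\tNM:i:0\n"
            "f2\t0\tchr1\t201\t255\t36M\t*\t0\t0\t" + "A" * 36 + "\t*\tNM:i:0\n"
            "f2\t256\tchr1\t501\t255\t36M\t*\t0\t0\t" + "A" * 36 + "\t*\tNM:i:0\n"
            "f3\t256\tchr1\t801\t255\t36M\t*\t0\t0\t" + "A" * 36 + "\t*\tNM:i:2\n"
            "f3\t0\tchr1\t901\t255\t36M\t*\t0\t0\t" + "A" * 36 + "\t*\tNM:i:1\n"
            "f4\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 36 + "\t*\n"
        )
        recs = {r.read_id: r for r in read_alignments_sam(str(sam))}
        assert recs["f1"].is_unique
        assert not recs["f2"].is_unique and len(recs["f2"].placements) == 2
        # only the minimal-NM hit of f3 is retained
        assert recs["f3"].is_unique
        assert recs["f3"].placements[0].start == 900
        assert not recs["f4"].aligned
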