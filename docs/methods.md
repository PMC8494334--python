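# Methods

This note records the models, defaults and numerical choices behind
`telocus`, and what the synthetic experiments can and cannot show.

## Synthetic data model

The generator emulates the statistical structure of a bulk paired-end
RNA-seq time course over staged disease progression: two conditions
(MUT/WT) × four timepoints (weeks 4, 8, 12, 17) × two replicates, 36 bp
paired reads by default, with 72 and 108 bp available for the read-length
experiments.

**Genome and annotation.** Chromosomes are i.i.d. random DNA (default
2 × 60 kb). Genes (default 10) have 2–4 exons of 350–700 bp separated by
400–900 bp introns. TE copies (default 80) derive from one consensus per
(class, subfamily): desk-scale lengths LINE 600–900, SINE 150–300,
LTR 400–700, DNA 250–400 bp. Placement targets fractions
exonic/intronic/intergenic = 0.12/0.33/0.55; when a category has no free
segment left the copy falls back to the next category (logged), and the
build fails only when nothing fits (`strict_placement` restores hard
failure). Copies never overlap each other; exonic copies overwrite exon
sequence and are therefore co-transcribed with their host gene by
construction.

**Divergence.** A copy is mutated from its consensus by substitutions only
(no indels), with transitions:transversions 2:1. The substitution fraction
is solved numerically so the expected Kimura 2-parameter distance equals the
target; the realized K2P of each copy is stored exactly. Substitution-only
mutation keeps the copy–consensus alignment trivial, which makes the K2P
oracle exact; real RepeatMasker divergences involve indels and alignment
choices that this model does not represent. 16.1% of copies are young, with
young divergence drawn as 8.5·u² percent (u uniform) — recently active
subfamilies cluster near 0% divergence, which is what creates genuine
multi-mapping — and old divergence uniform on 12–30%.

**Expression truth.** Half the copies are expressed. Each expressed locus
carries per-sample multipliers (log-normal noise, σ = 0.15 log2 units);
planted differentially expressed loci (default 8, young-biased at 32.3%)
multiply by 2^log2FC (|log2FC| ∈ [2.5, 4], 70% up) in MUT at one timepoint.
Genes are all expressed with σ = 0.7 log2 units of spread; coupled TEs
(default 4 pairs) follow their linked gene's multiplier raised to a planted
slope (1–2) with σ = 0.2 residual noise. True read counts are realized at
simulation time as Poisson around coverage·len/(2L)·multiplier, so the same
truth design serves every read length.

**Reads.** Fragment lengths are uniform between one read length and
2L + gap (gap default 50 bp), capped by the locus span; starts are uniform
within the locus. A fixed fragment length would leave the middle of short
loci unsequenced (the inter-mate gap never moves enough), which is
unphysical and starves the assembler, so a length distribution is used;
expected pair counts are unaffected. Sequencing errors are independent
substitutions (default 0.1%, a conventional short-read error rate; the
benchmark runs error-free). Base qualities are fixed (no quality model).

## Quantification

Alignment is splice-unaware exact-k-mer seeding (pigeonhole-complete:
max_mismatch+1 disjoint seeds, so every placement with ≤ 2 mismatches is
found) with full-length verification; all tied minimal-mismatch placements
are kept — no random tie-breaking anywhere, so results are deterministic.
Mates are placed jointly in FR orientation within a 1 kb fragment cap, and
the pair's joint mismatch count is minimized; fragments, not single mates,
are the counting unit.

EM: fragments whose best placements overlap exactly one annotated TE are
assigned wholly; a fragment compatible with locus set S is split
proportionally to θ_i = N_i/L_i (abundance per unit length, avoiding
long-locus bias), iterated from a uniform start until the largest per-locus
change is below 1e-6 (≤ 100 iterations). Total assigned weight equals the
number of TE-overlapping fragments exactly. The confidence score of a locus
is round(100·unique/total) — "unique" meaning fragments whose compatible
locus set is that single locus, because locus certainty (not genomic
placement uniqueness) is what the score must convey. The score formula of
the original locus-level quantifier is unpublished; the unique-read
percentage realizes its documented behaviour (driven by multi-mapping,
100 = fully confident, collapsing for young copies).

## Candidate filter

The assembler is a greedy exact suffix–prefix overlap merger (min overlap
20 bp): reads plus their reverse complements form the pool, the globally
longest overlap is merged repeatedly (lexicographic tie-breaks), and final
contigs are deduplicated by reverse-complement canonical form. No error
correction is attempted — adequate for the error-free benchmark reads it
serves. Implementation-wise a heap with lazy edge revalidation does the bulk
of the merging and a final all-pairs polish guarantees the no-merge-possible
fixed point. A locus becomes a candidate when a contig ≥ 2 read lengths has
a unique best placement overlapping it; ambiguous contigs are rejected
outright (conservative, matching the filter's purpose). The consensus
filter intersects score-thresholded quantifier calls with the candidate set.
The surrogate's thresholds (min overlap 20, min contig length 2L) are our
defaults, not published values of any external assembler-based tool.

## Differential expression

Size factors are median-of-ratios over features with nonzero counts in all
samples. The test is a deliberately small NB Wald test per timepoint
(2 MUT vs 2 WT): log2FC = log2((m̄_MUT+0.5)/(m̄_WT+0.5)) with a 0.5
pseudocount; variance via the delta method with an NB variance
μ + αμ². Per-feature method-of-moments dispersion estimates are useless at
n = 2 per group (their noise inflates the type-I error to 0.10–0.15), so —
as NB DE tools generally do — dispersion information is shared across
features: per-feature MoM estimates are clipped at 0, averaged into a
common dispersion, and floored at 0.01. Measured on NB simulations this
gives a type-I error of 0.03–0.06 at true dispersions 0.01–0.2 and power
≈ 1 for log2FC = 3 at mean 100. No shrinkage of fold changes, no
independent filtering, no outlier handling — this replicates the decision
rule (|log2FC| ≥ 2, BH-adjusted p < 0.05 within timepoint, inclusive
fold-change cutoffs with a `strict_lfc` flag), not DESeq2's internals.
Trajectories: constant (same non-ns call at ≥ 3 timepoints), switch (both
directions occur), transient (exactly one non-ns), none, complex.

## Age, context, association, competence

K2P excludes non-ACGT positions and raises on saturation. The young/old
boundary is inclusive (≤ 10%), with the threshold exposed. The enrichment
test is the two-sample χ² test of given proportions with Yates correction
on by default (mirroring R's `prop.test`); the correction can be disabled.

Context is strand-blind (flag to require strandedness), ≥ 1 bp of exon
overlap counts, gene span = min exon start to max exon end. Closest-gene
distance is the interval gap (signed, negative upstream of the gene start);
book-ended intervals report ±1 so intergenic distances are never 0; ties go
to the lexicographically smallest gene id and are logged. Distance is
measured to the gene span, not the TSS — the choice is documented rather
than biologically canonical.

Associations use OLS of gene on TE expression in log2(1+normalized counts)
(variance stabilization for least squares), all 16 samples pooled; condition
covariates are supported but off by default. BH is applied jointly across
all pairs; Pearson r is reported only for significant pairs. Gene counts
use the exon-overlap rule with cross-gene-ambiguous fragments dropped.

The competence screen interprets "no stop codon" as *some* stop-free
full-length frame (the screen asks whether any intact protein could be
encoded); a stricter all-frames reading is available via a flag. Length
gates use the lower bounds of the quoted full-length ranges (LINE 6000,
LTR 4000, DNA 900 bp); SINEs are non-autonomous regardless.

## Benchmark

Per (read length, seed): build genome → simulate one sample's TE-locus
reads at 20× → quantify → assemble/call candidates → threshold → score
against the truly expressed loci. Correctness is exact locus identity.
Defaults: read lengths {36, 72, 108}, thresholds {0, 50, 80, 90, 95, 99,
100}, both modes, 5 seeds, with per-cell means over seeds; a failing cell
is logged and skipped. The benchmark genome (120 copies, half expressed,
intergenic-heavy) is sized so the full grid runs in a few minutes on one
CPU; empty-prediction precision is defined as 0.

## What passing tests do and do not show

The generator reproduces the *mechanisms* the pipeline must survive —
multi-mapping from near-identical young copies, short-read ambiguity,
2-replicate designs, co-transcription of exonic copies — but not mammalian
genome scale, splicing, indels, GC or coverage bias, or real consensus
sequences. Green tests therefore validate the algorithms and their
qualitative behaviour (precision/recall orderings, score collapse on young
copies, exonic positive correlations), not any particular biological claim
about real data.

## Known limitations

- Substitution-only divergence and gap-free alignment; no indel tolerance
  in the aligner.
- The NB test's dispersion pooling assumes features share a dispersion
  scale; strong mean-dispersion trends are not modelled.
- The assembler is exact-overlap greedy; error-containing reads fragment
  contigs rather than being corrected.
- Desk-scale TE lengths mean LINEs can never pass their 6 kb competence
  gate in default synthetic runs; the screen's gates are exercised directly
  in its tests.
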