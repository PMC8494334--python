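"""Synthetic genome, TE annotation and paired-end read generator.

This module fabricates, with known ground truth, the kind of data the
rest of the pipeline analyses: a small genome carrying multi-exon genes
and TE copies derived from class-specific consensus sequences at
controlled Kimura divergence, and paired-end RNA-seq reads from a
2-condition x 4-timepoint x 2-replicate design (mutant vs wild type at
weeks 4, 8, 12, 17) with planted fold changes and planted gene~TE
couplings.

Divergence is substitution-only (no indels), so each copy stays
trivially aligned to its consensus and the K2P divergence of the
realized copy is exact.  Fragments are drawn uniformly within a locus,
sequencing errors are independent substitutions, and every read pair
carries its true genomic origin, which is what turns the generator into
a benchmark oracle.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from telocus.age import kimura2p
from telocus.ids import TEID, format_te_id

logger = logging.getLogger("telocus.synth")

__all__ = [
    "TEConsensus",
    "TEAnnotation",
    "Gene",
    "Sample",
    "TruthDesign",
    "ReadPair",
    "SampleReads",
    "SynthConfig",
    "GenomeBuild",
    "GenomeCapacityError",
    "random_dna",
    "revcomp",
    "mutate_from_consensus",
    "default_consensus_library",
    "build_genome",
    "simulate_sample",
    "simulate_reads",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

TE_CLASSES = ("LINE", "SINE", "LTR", "DNA")


class GenomeCapacityError(RuntimeError):
    """Requested placements exceed the genome's free space."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=length)])


@dataclass(frozen=True, slots=True)
class TEConsensus:
    consensus_id: str
    te_class: str
    family: str
    subfamily: str
    sequence: str

    def __post_init__(self):
        if not self.sequence or set(self.sequence) - set(_BASES):
            raise ValueError(f"consensus {self.consensus_id}: sequence must be non-empty ACGT")
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown TE class {self.te_class!r}")


@dataclass(slots=True)
class TEAnnotation:
    te_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    subfamily: str
    family: str
    te_class: str
    consensus_id: str
    divergence_pct: float
    score: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(slots=True)
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True, slots=True)
class Sample:
    condition: str  # "MUT" | "WT"
    timepoint: int  # weeks
    replicate: int

    @property
    def name(self) -> str:
        return f"{self.condition}_w{self.timepoint}_r{self.replicate}"


@dataclass(slots=True)
class TruthDesign:
    """Ground-truth expression design.

    ``te_multipliers``/``gene_multipliers`` hold per-sample relative
    expression factors (1.0 = the baseline coverage); actual true read
    counts are realized per read length at simulation time.
    """

    samples: list[Sample]
    expressed_loci: list[str]  # te_ids with nonzero baseline expression
    planted_de: dict[str, tuple[int, float]]  # te_id -> (timepoint, log2fc)
    coupled_pairs: dict[tuple[str, str], float]  # (gene_id, te_id) -> slope
    te_multipliers: dict[str, dict[str, float]]  # te_id -> sample -> factor
    gene_multipliers: dict[str, dict[str, float]]
    host_gene: dict[str, str] = field(default_factory=dict)  # exonic/intronic te -> gene
    closest_gene: dict[str, tuple[str, int]] = field(default_factory=dict)  # intergenic
    placement_context: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True, slots=True)
class ReadPair:
    read_id: str
    mate1: str
    mate2: str
    true_origin: tuple[str, int, int, str]  # (chrom, start, end, feature_id)


@dataclass(slots=True)
class SampleReads:
    sample: Sample
    read_pairs: list[ReadPair]
    te_true_counts: dict[str, int]
    gene_true_counts: dict[str, int]


@dataclass(slots=True)
class SynthConfig:
    """Knobs of the generator; defaults emulate the study conditions.

    Reads default to 36 bp paired-end at 20x per-locus coverage (the
    emulated dataset's geometry); the young-TE fraction defaults to
    0.161 (the genome-wide proportion the analysis reproduces) with
    young TEs biased into the differentially expressed set at 0.323.
    """

    n_chroms: int = 2
    chrom_length: int = 60_000
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (350, 700)
    intron_length: tuple[int, int] = (400, 900)
    intergenic_gap: tuple[int, int] = (1_000, 2_500)
    n_te: int = 80
    class_weights: tuple[float, float, float, float] = (0.14, 0.60, 0.17, 0.09)
    # consensus length ranges per class (desk-scale; real LINEs are ~6 kb)
    consensus_length: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "LINE": (600, 900),
            "SINE": (150, 300),
            "LTR": (400, 700),
            "DNA": (250, 400),
        }
    )
    subfamilies_per_class: int = 2
    placement_fractions: tuple[float, float, float] = (0.12, 0.33, 0.55)  # exon/intron/intergenic
    young_fraction: float = 0.161
    young_divergence: tuple[float, float] = (0.0, 8.5)
    # density of young divergence is skewed toward 0 (recently active
    # subfamilies have near-identical copies): d = lo + (hi-lo)*u^power
    young_divergence_power: float = 2.0
    old_divergence: tuple[float, float] = (12.0, 30.0)
    ts_tv_ratio: float = 2.0
    expressed_fraction: float = 0.5
    n_planted_de: int = 8
    de_young_fraction: float = 0.323
    de_log2fc: tuple[float, float] = (2.5, 4.0)
    de_up_fraction: float = 0.7
    n_coupled_pairs: int = 4
    coupling_slope: tuple[float, float] = (1.0, 2.0)
    strict_placement: bool = False
    te_log2_sd: float = 0.15
    gene_log2_sd: float = 0.7
    coupling_log2_sd: float = 0.2
    read_length: int = 36
    coverage: float = 20.0
    error_rate: float = 0.001
    frag_gap: int = 50
    timepoints: tuple[int, ...] = (4, 8, 12, 17)
    n_replicates: int = 2


@dataclass(slots=True)
class GenomeBuild:
    genome: dict[str, str]
    tes: list[TEAnnotation]
    genes: list[Gene]
    consensi: dict[str, TEConsensus]
    truth: TruthDesign
    config: SynthConfig


# ---------------------------------------------------------------------------
# consensus mutation


def _solve_substitution_rate(target_k: float, ts_tv: float) -> float:
    """Fraction of sites to substitute so the expected K2P equals target.

    With a fraction ``s`` of sites substituted and transitions chosen
    with probability ts_tv/(1+ts_tv), P = f_ts*s and Q = f_tv*s; invert
    K(s) numerically.
    """
    if target_k <= 0:
        return 0.0
    f_ts = ts_tv / (1.0 + ts_tv)
    f_tv = 1.0 / (1.0 + ts_tv)

    def k_of_s(s: float) -> float:
        w1 = 1.0 - 2.0 * f_ts * s - f_tv * s
        w2 = 1.0 - 2.0 * f_tv * s
        return -0.5 * math.log(w1 * math.sqrt(w2)) - target_k

    s_max = 0.999 / (2.0 * f_ts + f_tv)
    return float(brentq(k_of_s, 0.0, s_max * 0.999999))


def mutate_from_consensus(
    consensus: TEConsensus | str,
    target_divergence: float,
    seed: int,
    ts_tv_ratio: float = 2.0,
) -> tuple[str, float]:
    """Derive a TE copy from its consensus at a target K2P divergence.

    Substitution-only: a solved fraction of positions is mutated, split
    between transitions and transversions at ``ts_tv_ratio`` (default
    2:1), so the realized K2P divergence of the returned copy lands
    within ~1.5 percentage points of ``target_divergence`` for
    sequences >= 300 bp.  Deterministic given ``seed``.
    """
    seq = consensus.sequence if isinstance(consensus, TEConsensus) else consensus
    if not seq:
        raise ValueError("empty consensus sequence")
    if not 0 <= target_divergence <= 50:
        raise ValueError(f"target divergence {target_divergence} outside [0, 50]")
    if target_divergence == 0:
        return seq, 0.0
    rng = np.random.default_rng(seed)
    n = len(seq)
    s = _solve_substitution_rate(target_divergence / 100.0, ts_tv_ratio)
    n_sub = int(round(s * n))
    if n_sub == 0:
        return seq, 0.0
    f_ts = ts_tv_ratio / (1.0 + ts_tv_ratio)
    n_ts = int(round(n_sub * f_ts))
    sites = rng.choice(n, size=n_sub, replace=False)
    out = list(seq)
    for i, pos in enumerate(sites):
        base = out[pos]
        if i < n_ts:
            out[pos] = _TRANSITION[base]
        else:
            out[pos] = _TRANSVERSIONS[base][rng.integers(0, 2)]
    mutated = "".join(out)
    return mutated, kimura2p(mutated, seq)


def default_consensus_library(config: SynthConfig, rng: np.random.Generator) -> dict[str, TEConsensus]:
    """One random consensus per (class, subfamily index)."""
    lib: dict[str, TEConsensus] = {}
    for cls in TE_CLASSES:
        lo, hi = config.consensus_length[cls]
        for i in range(1, config.subfamilies_per_class + 1):
            length = int(rng.integers(lo, hi + 1))
            cid = f"{cls}-s{i}"
            lib[cid] = TEConsensus(
                consensus_id=cid,
                te_class=cls,
                family=f"{cls}-f{i}",
                subfamily=f"{cls}-s{i}",
                sequence=random_dna(rng, length),
            )
    return lib


# ---------------------------------------------------------------------------
# genome layout


def _carve(segments: list[tuple[int, int, str]], idx: int, start: int, end: int) -> None:
    """Remove [start, end) from the free segment at ``idx`` (in place)."""
    s0, e0, chrom = segments.pop(idx)
    if start - s0 > 0:
        segments.append((s0, start, chrom))
    if e0 - end > 0:
        segments.append((end, e0, chrom))
    segments.sort()


def _place_genes(config: SynthConfig, rng: np.random.Generator) -> list[Gene]:
    genes: list[Gene] = []
    cursors = {f"chr{i + 1}": 0 for i in range(config.n_chroms)}
    chrom_names = sorted(cursors)
    gi = 0
    while len(genes) < config.n_genes:
        chrom = chrom_names[gi % len(chrom_names)]
        gi += 1
        gap = int(rng.integers(*config.intergenic_gap))
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        pos = cursors[chrom] + gap
        exons = []
        for j in range(n_ex):
            elen = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            exons.append((pos, pos + elen))
            pos += elen
            if j < n_ex - 1:
                pos += int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
        if pos >= config.chrom_length - 200:
            if all(c > config.chrom_length - 3_500 for c in cursors.values()):
                raise GenomeCapacityError(
                    f"cannot place {config.n_genes} genes in "
                    f"{config.n_chroms} x {config.chrom_length} bp"
                )
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        gene = Gene(
            gene_id=f"gene{len(genes) + 1:04d}",
            chrom=chrom,
            start=exons[0][0],
            end=exons[-1][1],
            strand=strand,
            exons=exons,
        )
        genes.append(gene)
        cursors[chrom] = gene.end
    return genes


def build_genome(config: SynthConfig, seed: int) -> GenomeBuild:
    """Fabricate genome + annotations + expression truth.

    TE copies never overlap one another; each copy's realized K2P
    divergence from its consensus is stored on its annotation (and in
    the BED score as divergence x 10, rounded).  Placement is
    hierarchical: a configurable fraction of copies is dropped inside
    exons (co-transcribed with the host gene), inside introns, or in
    intergenic space.
    """
    rng = np.random.default_rng(seed)
    genes = _place_genes(config, rng)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_arrays = {c: bytearray(random_dna(rng, config.chrom_length).encode()) for c in chrom_names}
    consensi = default_consensus_library(config, rng)

    # free segments by context
    exon_free: list[tuple[int, int, str]] = []
    intron_free: list[tuple[int, int, str]] = []
    intergenic_free: list[tuple[int, int, str]] = []
    gene_by_interval: dict[tuple[str, int, int], str] = {}
    for g in genes:
        for s, e in g.exons:
            exon_free.append((s, e, g.chrom))
            gene_by_interval[(g.chrom, s, e)] = g.gene_id
        for (s0, e0), (s1, _) in zip(g.exons, g.exons[1:]):
            intron_free.append((e0, s1, g.chrom))
            gene_by_interval[(g.chrom, e0, s1)] = g.gene_id
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for g in genes:
        spans[g.chrom].append((g.start, g.end))
    for c in chrom_names:
        cur = 0
        for s, e in sorted(spans[c]):
            if s - cur > 0:
                intergenic_free.append((cur, s, c))
            cur = e
        if config.chrom_length - cur > 0:
            intergenic_free.append((cur, config.chrom_length, c))
    exon_free.sort()
    intron_free.sort()
    intergenic_free.sort()

    cids = sorted(consensi)
    class_of = {cid: consensi[cid].te_class for cid in cids}
    weights = dict(zip(("LINE", "SINE", "LTR", "DNA"), config.class_weights))
    cid_w = np.array([weights[class_of[c]] for c in cids], dtype=float)
    cid_w /= cid_w.sum()
    ctx_names = ("Exonic", "Intronic", "Intergenic")
    free_by_ctx = {"Exonic": exon_free, "Intronic": intron_free, "Intergenic": intergenic_free}

    tes: list[TEAnnotation] = []
    placement_context: dict[str, str] = {}
    host_gene: dict[str, str] = {}
    closest_gene: dict[str, tuple[str, int]] = {}
    margin = 10  # keep copies off segment edges so contexts stay unambiguous
    fallback = {
        "Exonic": ("Exonic", "Intronic", "Intergenic"),
        "Intronic": ("Intronic", "Intergenic", "Exonic"),
        "Intergenic": ("Intergenic", "Intronic", "Exonic"),
    }
    for _ in range(config.n_te):
        want = str(rng.choice(ctx_names, p=np.array(config.placement_fractions)))
        young = rng.random() < config.young_fraction
        if young:
            lo, hi = config.young_divergence
            target_div = lo + (hi - lo) * float(rng.random()) ** config.young_divergence_power
        else:
            target_div = float(rng.uniform(*config.old_divergence))
        placed = False
        for _attempt in range(60):
            cid = str(rng.choice(cids, p=cid_w))
            cons = consensi[cid]
            te_len = len(cons.sequence)
            ctx, fit = want, []
            for ctx in fallback[want] if not config.strict_placement else (want,):
                segs = free_by_ctx[ctx]
                fit = [i for i, (s, e, _) in enumerate(segs) if e - s >= te_len + 2 * margin]
                if fit:
                    break
            if not fit:
                continue
            if ctx != want:
                logger.info("context %s full; placing a %s copy in %s", want, cid, ctx)
            segs = free_by_ctx[ctx]
            idx = fit[int(rng.integers(0, len(fit)))]
            s0, e0, chrom = segs[idx]
            start = int(rng.integers(s0 + margin, e0 - te_len - margin + 1))
            end = start + te_len
            copy, realized = mutate_from_consensus(
                cons, target_div, seed=int(rng.integers(0, 2**31 - 1)),
                ts_tv_ratio=config.ts_tv_ratio,
            )
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = copy if strand == "+" else revcomp(copy)
            chrom_arrays[chrom][start:end] = inserted.encode()
            score = int(round(realized * 10))
            te_id = format_te_id(
                TEID(chrom, start, end, cons.subfamily, cons.family, cons.te_class, score, strand)
            )
            tes.append(
                TEAnnotation(
                    te_id=te_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    subfamily=cons.subfamily,
                    family=cons.family,
                    te_class=cons.te_class,
                    consensus_id=cid,
                    divergence_pct=realized,
                    score=score,
                )
            )
            placement_context[te_id] = str(ctx)
            if ctx in ("Exonic", "Intronic"):
                seg_key = (chrom, s0, e0)
                # the original (uncarved) interval key may be gone; search spans
                gid = gene_by_interval.get(seg_key)
                if gid is None:
                    for g in genes:
                        if g.chrom == chrom and g.start <= start and end <= g.end:
                            gid = g.gene_id
                            break
                host_gene[te_id] = gid or ""
            else:
                best: tuple[int, str] | None = None
                for g in genes:
                    if g.chrom != chrom:
                        continue
                    if end <= g.start:
                        d = -(g.start - end)  # upstream of gene start
                    elif g.end <= start:
                        d = start - g.end
                    else:  # pragma: no cover - cannot happen for intergenic
                        d = 0
                    if best is None or abs(d) < abs(best[0]) or (
                        abs(d) == abs(best[0]) and g.gene_id < best[1]
                    ):
                        best = (d, g.gene_id)
                if best is not None:
                    closest_gene[te_id] = (best[1], best[0])
            _carve(segs, idx, start, end)
            placed = True
            break
        if not placed:
            raise GenomeCapacityError(
                f"no free segment (requested context {want}) can host another "
                f"TE copy (placed {len(tes)}/{config.n_te})"
            )

    genome = {c: chrom_arrays[c].decode() for c in chrom_names}
    truth = _design_truth(config, rng, tes, genes, placement_context, host_gene, closest_gene)
    return GenomeBuild(
        genome=genome, tes=tes, genes=genes, consensi=consensi, truth=truth, config=config
    )


def _design_truth(
    config: SynthConfig,
    rng: np.random.Generator,
    tes: list[TEAnnotation],
    genes: list[Gene],
    placement_context: dict[str, str],
    host_gene: dict[str, str],
    closest_gene: dict[str, tuple[str, int]],
) -> TruthDesign:
    samples = [
        Sample(cond, tp, rep)
        for tp in config.timepoints
        for cond in ("MUT", "WT")
        for rep in range(1, config.n_replicates + 1)
    ]
    te_ids = [t.te_id for t in tes]
    n_expr = int(round(config.expressed_fraction * len(te_ids)))
    expressed = sorted(rng.choice(te_ids, size=n_expr, replace=False).tolist())

    # planted DE, with young copies over-represented at de_young_fraction
    div = {t.te_id: t.divergence_pct for t in tes}
    young_expr = [t for t in expressed if div[t] <= 10.0]
    old_expr = [t for t in expressed if div[t] > 10.0]
    planted_de: dict[str, tuple[int, float]] = {}
    pool_young = list(young_expr)
    pool_old = list(old_expr)
    for _ in range(min(config.n_planted_de, len(expressed))):
        take_young = pool_young and (rng.random() < config.de_young_fraction or not pool_old)
        pool = pool_young if take_young else pool_old
        te = pool.pop(int(rng.integers(0, len(pool))))
        tp = int(rng.choice(config.timepoints))
        sign = 1.0 if rng.random() < config.de_up_fraction else -1.0
        lfc = sign * float(rng.uniform(*config.de_log2fc))
        planted_de[te] = (tp, lfc)

    # per-sample gene multipliers (log-normal across samples)
    gene_multipliers: dict[str, dict[str, float]] = {}
    for g in genes:
        base = float(2.0 ** rng.normal(0.0, config.gene_log2_sd))
        gene_multipliers[g.gene_id] = {
            s.name: base * float(2.0 ** rng.normal(0.0, config.gene_log2_sd)) for s in samples
        }

    # gene~TE couplings: intronic/intergenic expressed TEs follow their
    # linked gene's expression with a planted slope (in log2 space)
    coupled_pairs: dict[tuple[str, str], float] = {}
    candidates = [
        t for t in expressed
        if placement_context.get(t) in ("Intronic", "Intergenic") and t not in planted_de
    ]
    rng.shuffle(candidates)
    for te in candidates[: config.n_coupled_pairs]:
        gid = host_gene.get(te) or closest_gene.get(te, ("", 0))[0]
        if not gid:
            continue
        coupled_pairs[(gid, te)] = float(rng.uniform(*config.coupling_slope))

    te_multipliers: dict[str, dict[str, float]] = {}
    coupled_te = {te: (gid, slope) for (gid, te), slope in coupled_pairs.items()}
    for te in expressed:
        mult: dict[str, float] = {}
        for s in samples:
            m = float(2.0 ** rng.normal(0.0, config.te_log2_sd))
            if te in planted_de:
                tp, lfc = planted_de[te]
                if s.condition == "MUT" and s.timepoint == tp:
                    m *= 2.0 ** lfc
            if te in coupled_te:
                gid, slope = coupled_te[te]
                m *= gene_multipliers[gid][s.name] ** slope * float(
                    2.0 ** rng.normal(0.0, config.coupling_log2_sd)
                )
            mult[s.name] = m
        te_multipliers[te] = mult

    return TruthDesign(
        samples=samples,
        expressed_loci=expressed,
        planted_de=planted_de,
        coupled_pairs=coupled_pairs,
        te_multipliers=te_multipliers,
        gene_multipliers=gene_multipliers,
        host_gene=host_gene,
        closest_gene=closest_gene,
        placement_context=placement_context,
    )


# ---------------------------------------------------------------------------
# read simulation


def _fragment_reads(
    genome: dict[str, str],
    chrom: str,
    lo: int,
    hi: int,
    strand: str,
    n_frags: int,
    read_length: int,
    frag_len: int,
    rng: np.random.Generator,
) -> list[tuple[int, int, str, str]]:
    """Uniform fragments within [lo, hi); returns (start, end, mate1, mate2).

    Fragment lengths are drawn uniformly between one read length and
    ``frag_len`` (the maximum insert), capped by the locus span, so
    every position of a short locus can be sequenced; shorter fragments
    simply have overlapping mates.
    """
    out = []
    span = hi - lo
    seq = genome[chrom]
    lmax = min(frag_len, span)
    lmin = min(read_length, lmax)
    flens = rng.integers(lmin, lmax + 1, size=n_frags)
    for flen in flens:
        flen = int(flen)
        st = int(rng.integers(lo, hi - flen + 1)) if span > flen else lo
        frag = seq[st : st + flen]
        if strand == "+":
            m1, m2 = frag[:read_length], revcomp(frag[-read_length:])
        else:
            m1, m2 = revcomp(frag[-read_length:]), frag[:read_length]
        out.append((st, st + flen, m1, m2))
    return out


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for p in pos:
        cur = out[p]
        alts = [b for b in _BASES if b != cur]
        out[p] = alts[rng.integers(0, 3)]
    return "".join(out)


def simulate_sample(
    build: GenomeBuild,
    sample: Sample,
    read_length: int | None = None,
    coverage: float | None = None,
    error_rate: float | None = None,
    seed: int = 0,
    te_only: bool = False,
) -> SampleReads:
    """Simulate paired-end reads for one sample.

    With ``te_only`` no gene-derived reads are produced (the geometry
    of the locus-recovery and precision/recall experiments, which draw
    coverage from TE loci alone).

    The expected pair count of a locus is
    ``coverage * locus_length / (2 * read_length)`` times its truth
    multiplier (Poisson realized); fragment starts are uniform within
    the locus; sequencing errors are independent substitutions.  Loci
    shorter than the read length are skipped with a logged warning.
    """
    cfg = build.config
    L = read_length if read_length is not None else cfg.read_length
    cov = coverage if coverage is not None else cfg.coverage
    err = error_rate if error_rate is not None else cfg.error_rate
    if not 0 <= err <= 0.05:
        raise ValueError(f"error rate {err} outside [0, 0.05]")
    rng = np.random.default_rng([seed, zlib.crc32(sample.name.encode())])
    frag_len = 2 * L + cfg.frag_gap
    pairs: list[ReadPair] = []
    te_true: dict[str, int] = {}
    gene_true: dict[str, int] = {}
    te_by_id = {t.te_id: t for t in build.tes}

    for te_id in build.truth.expressed_loci:
        te = te_by_id[te_id]
        if te.length < L:
            logger.warning("locus %s (%d bp) shorter than read length %d; skipped", te_id, te.length, L)
            continue
        lam = cov * te.length / (2.0 * L) * build.truth.te_multipliers[te_id][sample.name]
        n = int(rng.poisson(lam))
        te_true[te_id] = n
        if n == 0:
            continue
        frags = _fragment_reads(build.genome, te.chrom, te.start, te.end, te.strand, n, L, frag_len, rng)
        for i, (fs, fe, m1, m2) in enumerate(frags):
            pairs.append(
                ReadPair(
                    read_id=f"{sample.name}:te:{te_id}:{i}",
                    mate1=_apply_errors(m1, err, rng),
                    mate2=_apply_errors(m2, err, rng),
                    true_origin=(te.chrom, fs, fe, te_id),
                )
            )

    for gene in build.genes if not te_only else []:
        mult = build.truth.gene_multipliers[gene.gene_id][sample.name]
        exons = [(s, e) for s, e in gene.exons if e - s >= L]
        if not exons:
            continue
        lam = cov * sum(e - s for s, e in exons) / (2.0 * L) * mult
        n = int(rng.poisson(lam))
        gene_true[gene.gene_id] = n
        if n == 0:
            continue
        lens = np.array([e - s for s, e in exons], dtype=float)
        alloc = rng.multinomial(n, lens / lens.sum())
        i = 0
        for (es, ee), k in zip(exons, alloc):
            if k == 0:
                continue
            frags = _fragment_reads(build.genome, gene.chrom, es, ee, gene.strand, int(k), L, frag_len, rng)
            for fs, fe, m1, m2 in frags:
                pairs.append(
                    ReadPair(
                        read_id=f"{sample.name}:gene:{gene.gene_id}:{i}",
                        mate1=_apply_errors(m1, err, rng),
                        mate2=_apply_errors(m2, err, rng),
                        true_origin=(gene.chrom, fs, fe, gene.gene_id),
                    )
                )
                i += 1
    return SampleReads(sample=sample, read_pairs=pairs, te_true_counts=te_true, gene_true_counts=gene_true)


def simulate_reads(
    build: GenomeBuild,
    read_length: int | None = None,
    coverage: float | None = None,
    error_rate: float | None = None,
    seed: int = 0,
    samples: Sequence[Sample] | None = None,
    te_only: bool = False,
) -> dict[str, SampleReads]:
    """Simulate all (or selected) samples of the design; deterministic per seed."""
    chosen = list(samples) if samples is not None else build.truth.samples
    out: dict[str, SampleReads] = {}
    for i, s in enumerate(chosen):
        out[s.name] = simulate_sample(
            build, s, read_length=read_length, coverage=coverage,
            error_rate=error_rate, seed=seed + 1000 * i, te_only=te_only,
        )
    return out
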