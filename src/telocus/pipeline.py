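"""End-to-end orchestration: synth -> quant -> filter -> DE -> age ->
context -> assoc -> screen (-> bench), with a reproducible manifest.

Every stage writes sorted TSVs (byte-identical across reruns with the
same config and seed) plus the figures of the corresponding analysis;
the manifest records the package version, the full configuration, the
seed and per-stage record counts, which is sufficient to reproduce the
run exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

import telocus
from telocus import assoc as assoc_mod
from telocus import bench as bench_mod
from telocus import context as context_mod
from telocus import diffexp, io, plots, screen
from telocus.age import label_age, proportion_test
from telocus.filtercand import assemble_contigs, call_candidates, consensus_filter
from telocus.quant import GenomeIndex, LocusQuant, align_reads, count_genes, em_assign, score_locus
from telocus.synth import GenomeBuild, SynthConfig, build_genome, revcomp, simulate_reads

logger = logging.getLogger("telocus.pipeline")

__all__ = ["RunConfig", "StageError", "run_all", "load_config", "save_config"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(slots=True)
class RunConfig:
    """All pipeline parameters with their documented defaults."""

    outdir: str = "telocus_out"
    seed: int = 1
    synth: SynthConfig = field(default_factory=SynthConfig)
    max_mismatch: int = 2
    max_frag: int = 1000
    score_threshold: int = 100
    min_overlap: int = 20
    min_contig_len: int | None = None
    max_assembly_fragments: int = 5000
    alpha: float = 0.05
    lfc_cut: float = 2.0
    strict_lfc: bool = False
    age_threshold: float = 10.0
    all_frames: bool = False
    write_fastq: bool = False
    run_bench: bool = False
    bench_read_lengths: tuple[int, ...] = (36, 72, 108)
    bench_thresholds: tuple[int, ...] = (0, 50, 80, 90, 95, 99, 100)
    bench_seeds: tuple[int, ...] = (1, 2, 3, 4, 5)


def _tuplify(value: Any) -> Any:
    if isinstance(value, list):
        return tuple(_tuplify(v) for v in value)
    if isinstance(value, dict):
        return {k: _tuplify(v) for k, v in value.items()}
    return value


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config; missing keys take their defaults (round-trips
    with :func:`save_config`)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    synth_raw = raw.pop("synth", {})
    synth = SynthConfig(**{k: _tuplify(v) for k, v in synth_raw.items()})
    return RunConfig(synth=synth, **{k: _tuplify(v) for k, v in raw.items()})


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _te_sequence(build: GenomeBuild, te) -> str:
    s = build.genome[te.chrom][te.start : te.end]
    return s if te.strand == "+" else revcomp(s)


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis; returns the in-memory stage results.

    On stage failure a :class:`StageError` naming the stage is raised
    and the partial outputs already written are preserved.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("telocus").addHandler(fh)
    manifest: dict[str, Any] = {
        "package": "telocus",
        "version": telocus.__version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    results: dict[str, Any] = {}
    stage = "synth"
    try:
        # ------------------------------------------------------------- synth
        build = build_genome(config.synth, seed=config.seed)
        results["build"] = build
        io.write_fasta(build.genome, out / "genome.fa")
        io.write_te_bed(build.tes, out / "te_annotation.bed")
        io.write_gene_gff3(build.genes, out / "genes.gff3")
        sims = simulate_reads(build, seed=config.seed)
        results["sims"] = sims
        truth_rows = [
            {"te_id": t, "sample": s, "true_count": c}
            for s in sorted(sims)
            for t, c in sorted(sims[s].te_true_counts.items())
        ]
        _write_tsv(pd.DataFrame(truth_rows, columns=["te_id", "sample", "true_count"]),
                   out / "truth_te_counts.tsv")
        de_rows = [
            {"te_id": t, "timepoint": tp, "log2fc": fc}
            for t, (tp, fc) in sorted(build.truth.planted_de.items())
        ]
        _write_tsv(pd.DataFrame(de_rows, columns=["te_id", "timepoint", "log2fc"]),
                   out / "truth_planted_de.tsv")
        if config.write_fastq:
            for name, sim in sorted(sims.items()):
                io.write_fastq(sim.read_pairs, out / f"{name}_1.fastq", out / f"{name}_2.fastq")
        manifest["stages"]["synth"] = {
            "n_tes": len(build.tes), "n_genes": len(build.genes),
            "n_samples": len(sims),
            "n_read_pairs": int(sum(len(s.read_pairs) for s in sims.values())),
        }

        # ------------------------------------------------------------- quant
        stage = "quant"
        index = GenomeIndex(build.genome)
        te_counts: dict[str, dict[str, float]] = {}
        gene_counts: dict[str, dict[str, int]] = {}
        score_rows = []
        agg: dict[str, LocusQuant] = {}
        all_records = {}
        for name in sorted(sims):
            records = align_reads(
                sims[name].read_pairs, index,
                max_mismatch=config.max_mismatch, max_frag=config.max_frag,
            )
            all_records[name] = records
            quants = em_assign(records, build.tes)
            te_counts[name] = {q.te_id: q.total_count for q in quants}
            gene_counts[name] = count_genes(records, build.genes)
            for q in quants:
                score_rows.append(
                    {"sample": name, "te_id": q.te_id, "total_count": q.total_count,
                     "unique_count": q.unique_count, "score": q.score}
                )
                a = agg.setdefault(q.te_id, LocusQuant(q.te_id, 0.0, 0))
                a.total_count += q.total_count
                a.unique_count += q.unique_count
        for a in agg.values():
            a.score = score_locus(a)
        _write_tsv(pd.DataFrame(score_rows).sort_values(["sample", "te_id"]),
                   out / "quant_scores.tsv")
        te_ids = sorted({t.te_id for t in build.tes})
        gene_ids = sorted(g.gene_id for g in build.genes)
        sample_names = sorted(sims)
        te_mat = pd.DataFrame(
            {s: [te_counts[s].get(t, 0.0) for t in te_ids] for s in sample_names},
            index=pd.Index(te_ids, name="feature_id"),
        )
        gene_mat = pd.DataFrame(
            {s: [gene_counts[s].get(g, 0) for g in gene_ids] for s in sample_names},
            index=pd.Index(gene_ids, name="feature_id"),
        )
        _write_tsv(te_mat.round(6).reset_index(), out / "counts_te.tsv")
        _write_tsv(gene_mat.reset_index(), out / "counts_gene.tsv")
        results["te_counts"] = te_mat
        results["gene_counts"] = gene_mat
        results["agg_quants"] = agg
        manifest["stages"]["quant"] = {
            "n_te_features": len(te_ids), "n_gene_features": len(gene_ids),
        }

        # -------------------------------------------------------- filtercand
        stage = "filtercand"
        rng = np.random.default_rng(config.seed + 104729)
        pool = [rp for name in sorted(sims) for rp in sims[name].read_pairs]
        if len(pool) > config.max_assembly_fragments:
            keep = rng.choice(len(pool), size=config.max_assembly_fragments, replace=False)
            pool = [pool[i] for i in sorted(keep)]
        contigs = assemble_contigs(pool, min_overlap=config.min_overlap)
        candidates = call_candidates(
            contigs, index, build.tes,
            min_contig_len=config.min_contig_len,
            read_length=config.synth.read_length,
            max_mismatch=config.max_mismatch,
        )
        high_conf = consensus_filter(
            list(agg.values()), candidates, score_threshold=config.score_threshold
        )
        with open(out / "contigs.fa", "w") as fa:
            for c in contigs:
                fa.write(f">{c.contig_id} n_reads={c.n_reads}\n{c.sequence}\n")
        _write_tsv(pd.DataFrame({"te_id": sorted(candidates)}), out / "candidates.tsv")
        _write_tsv(pd.DataFrame({"te_id": sorted(high_conf)}), out / "high_confidence.tsv")
        results["candidates"] = candidates
        results["high_confidence"] = high_conf
        manifest["stages"]["filtercand"] = {
            "n_contigs": len(contigs), "n_candidates": len(candidates),
            "n_high_confidence": len(high_conf),
        }

        # ----------------------------------------------------------- diffexp
        stage = "diffexp"
        combined = pd.concat([te_mat, gene_mat])
        de = diffexp.de_timecourse(
            combined, build.truth.samples,
            lfc_cut=config.lfc_cut, alpha=config.alpha, strict_lfc=config.strict_lfc,
        )
        de = de.sort_values(["feature_id", "timepoint"]).reset_index(drop=True)
        _write_tsv(de, out / "de_results.tsv")
        te_de = de[de["feature_id"].isin(te_ids)]
        de_tes = sorted(te_de.loc[te_de["call"] != "ns", "feature_id"].unique())
        for tp in sorted(te_de["timepoint"].unique()):
            plots.volcano_plot(te_de, tp, out / f"volcano_w{tp}.png",
                               lfc_cut=config.lfc_cut, alpha=config.alpha)
        results["de"] = de
        results["de_tes"] = de_tes
        manifest["stages"]["diffexp"] = {"n_de_tes": len(de_tes)}

        # --------------------------------------------------------------- age
        stage = "age"
        labels = [
            label_age(t.divergence_pct, threshold=config.age_threshold, te_id=t.te_id)
            for t in build.tes
        ]
        lab_df = pd.DataFrame([dataclasses.asdict(l) for l in labels]).sort_values("te_id")
        _write_tsv(lab_df, out / "age_labels.tsv")
        young = {l.te_id for l in labels if l.label == "young"}
        k2, n2 = len(young), len(labels)
        k1 = len([t for t in de_tes if t in young])
        n1 = len(de_tes)
        if n1 > 0:
            test = proportion_test(k1, n1, k2, n2)
            age_row = {"k_young_de": k1, "n_de": n1, "k_young_all": k2, "n_all": n2,
                       "p1": test.p1, "p2": test.p2, "chi2": test.chi2, "pvalue": test.pvalue}
        else:
            age_row = {"k_young_de": 0, "n_de": 0, "k_young_all": k2, "n_all": n2,
                       "p1": float("nan"), "p2": k2 / n2, "chi2": float("nan"),
                       "pvalue": float("nan")}
        _write_tsv(pd.DataFrame([age_row]), out / "age_test.tsv")
        div_by_id = {t.te_id: t.divergence_pct for t in build.tes}
        plots.divergence_histograms(
            list(div_by_id.values()), [div_by_id[t] for t in de_tes],
            out / "divergence_hist.png", threshold=config.age_threshold,
        )
        results["age_test"] = age_row
        manifest["stages"]["age"] = {"n_young": k2, "n_young_de": k1}

        # ----------------------------------------------------------- context
        stage = "context"
        links = context_mod.classify_all(build.tes, build.genes)
        ctx_df = pd.DataFrame([dataclasses.asdict(l) for l in links]).sort_values("te_id")
        _write_tsv(ctx_df, out / "context.tsv")
        ctx_counts = ctx_df["context"].value_counts().to_dict()
        plots.context_pie(ctx_counts, out / "context_pie.png")
        results["context"] = links
        manifest["stages"]["context"] = ctx_counts

        # ------------------------------------------------------------- assoc
        stage = "assoc"
        _, norm = diffexp.normalize(combined)
        log_expr = assoc_mod.log_expression(norm)
        pairs = [l for l in links if l.te_id in set(de_tes)]
        assoc_results = assoc_mod.associate_all(
            pairs,
            log_expr.loc[[g for g in gene_ids]],
            log_expr.loc[[t for t in te_ids]],
            alpha=config.alpha,
        )
        assoc_df = pd.DataFrame(
            [dataclasses.asdict(a) for a in assoc_results],
            columns=["gene_id", "te_id", "context", "slope", "slope_se",
                     "pvalue", "padj", "pearson_r", "n_samples"],
        ).sort_values(["gene_id", "te_id"]).reset_index(drop=True)
        _write_tsv(assoc_df, out / "assoc.tsv")
        if len(assoc_df):
            plots.correlation_dotplot(assoc_df, out / "assoc_dotplot.png")
        results["assoc"] = assoc_df
        manifest["stages"]["assoc"] = {
            "n_pairs": len(assoc_df),
            "n_significant": int((assoc_df["padj"] < config.alpha).sum()) if len(assoc_df) else 0,
        }

        # ------------------------------------------------------------ screen
        stage = "screen"
        te_by_id = {t.te_id: t for t in build.tes}
        comp_rows = []
        for t in de_tes:
            te = te_by_id[t]
            res = screen.competence(
                te.te_class, _te_sequence(build, te), te_id=t, all_frames=config.all_frames
            )
            comp_rows.append(dataclasses.asdict(res))
        comp_df = pd.DataFrame(
            comp_rows,
            columns=["te_id", "te_class", "length", "has_stop_free_frame",
                     "length_ok", "autonomous", "verdict"],
        ).sort_values("te_id").reset_index(drop=True)
        _write_tsv(comp_df, out / "screen.tsv")
        results["screen"] = comp_df
        manifest["stages"]["screen"] = {
            "n_screened": len(comp_df),
            "n_stop_free": int(comp_df["has_stop_free_frame"].sum()) if len(comp_df) else 0,
        }

        # ------------------------------------------------------------- bench
        if config.run_bench:
            stage = "bench"
            bcfg = bench_mod.BenchConfig(
                read_lengths=config.bench_read_lengths,
                thresholds=config.bench_thresholds,
                seeds=config.bench_seeds,
            )
            grid = bench_mod.sweep(bcfg)
            summary = bench_mod.summarize(grid)
            _write_tsv(grid, out / "bench_grid.tsv")
            _write_tsv(summary, out / "bench_summary.tsv")
            plots.benchmark_bars(summary, out / "bench_bars.png")
            results["bench"] = summary
            manifest["stages"]["bench"] = {"n_grid_rows": len(grid)}
    except Exception as exc:
        logger.error("stage %s failed", stage, exc_info=True)
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as mh:
            json.dump(manifest, mh, indent=2, sort_keys=True, default=str)
        raise StageError(stage, exc) from exc
    finally:
        logging.getLogger("telocus").removeHandler(fh)
        fh.close()

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as mh:
        json.dump(manifest, mh, indent=2, sort_keys=True, default=str)
    results["manifest"] = manifest
    return results
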