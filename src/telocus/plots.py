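"""Figure helpers: volcano, divergence histograms, context pie, r dot plot,
precision/recall bars.  All functions write a PNG and return the path."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "volcano_plot",
    "divergence_histograms",
    "context_pie",
    "correlation_dotplot",
    "benchmark_bars",
]

_CALL_COLORS = {"up": "tab:red", "down": "tab:blue", "ns": "0.6"}


def volcano_plot(
    de: pd.DataFrame, timepoint: int, path: str | Path,
    lfc_cut: float = 2.0, alpha: float = 0.05,
) -> Path:
    """Volcano of one timepoint's results with up/down/ns counts annotated."""
    sub = de[de["timepoint"] == timepoint]
    x = sub["log2fc"].to_numpy()
    y = -np.log10(np.maximum(sub["padj"].to_numpy(dtype=float), 1e-300))
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for call in ("ns", "down", "up"):
        m = (sub["call"] == call).to_numpy()
        ax.scatter(x[m], y[m], s=8, c=_CALL_COLORS[call], label=call, alpha=0.7)
    ax.axhline(-np.log10(alpha), ls="--", c="k", lw=0.8)
    ax.axvline(lfc_cut, ls="--", c="k", lw=0.8)
    ax.axvline(-lfc_cut, ls="--", c="k", lw=0.8)
    n_up = int((sub["call"] == "up").sum())
    n_down = int((sub["call"] == "down").sum())
    n_ns = int((sub["call"] == "ns").sum())
    n_all = max(len(sub), 1)
    ax.set_title(f"week {timepoint}")
    ax.text(0.02, 0.98, f"{n_down}\n{100 * n_down / n_all:.1f}%",
            transform=ax.transAxes, va="top", color="tab:blue")
    ax.text(0.5, 0.98, f"{n_ns}", transform=ax.transAxes, va="top", ha="center", color="0.4")
    ax.text(0.98, 0.98, f"{n_up}\n{100 * n_up / n_all:.1f}%",
            transform=ax.transAxes, va="top", ha="right", color="tab:red")
    ax.set_xlabel("log2(fold change)")
    ax.set_ylabel("-log10(adjusted p)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def divergence_histograms(
    all_div: Sequence[float], de_div: Sequence[float], path: str | Path,
    threshold: float = 10.0,
) -> Path:
    """Side-by-side Kimura divergence histograms (all TEs vs DE-TEs)."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharey=False)
    for ax, vals, title in zip(axes, (all_div, de_div), ("All TEs", "DE-TEs")):
        vals = np.asarray(list(vals), dtype=float)
        ax.hist(vals, bins=np.arange(0, 35, 1), color="0.5")
        ax.axvline(threshold, ls="--", c="k")
        frac = float((vals <= threshold).mean()) if len(vals) else 0.0
        ax.text(0.97, 0.95, f"young: {100 * frac:.1f}%", transform=ax.transAxes,
                ha="right", va="top")
        ax.set_title(title)
        ax.set_xlabel("Kimura divergence (%)")
    axes[0].set_ylabel("TE copies")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def context_pie(context_counts: dict[str, int], path: str | Path) -> Path:
    labels = [k for k in ("Exonic", "Intronic", "Intergenic") if context_counts.get(k)]
    sizes = [context_counts[k] for k in labels]
    fig, ax = plt.subplots(figsize=(4, 4))
    if sizes:
        ax.pie(sizes, labels=labels, autopct="%1.1f%%")
    ax.set_title("TE genomic context")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def correlation_dotplot(assoc: pd.DataFrame, path: str | Path) -> Path:
    """Pearson r of significant gene-TE pairs, grouped by context."""
    fig, ax = plt.subplots(figsize=(5, 4))
    order = ["Exonic", "Intronic", "Intergenic"]
    sig = assoc.dropna(subset=["pearson_r"])
    for i, ctx in enumerate(order):
        vals = sig.loc[sig["context"] == ctx, "pearson_r"].to_numpy()
        if len(vals):
            jitter = (np.arange(len(vals)) - len(vals) / 2) * 0.02
            ax.scatter(np.full(len(vals), i) + jitter, vals, s=25)
    ax.axhline(0, c="k", lw=0.8)
    ax.set_xticks(range(len(order)), order)
    ax.set_ylabel("Pearson r (significant pairs)")
    ax.set_ylim(-1.05, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def benchmark_bars(summary: pd.DataFrame, path: str | Path) -> Path:
    """Grouped precision (red) / recall (blue) bars; one panel per threshold,
    one row per mode."""
    thresholds = sorted(summary["score_threshold"].unique())
    modes = list(summary["mode"].unique())
    fig, axes = plt.subplots(
        len(modes), len(thresholds), figsize=(2.2 * len(thresholds), 2.6 * len(modes)),
        sharey=True, squeeze=False,
    )
    for r, mode in enumerate(modes):
        for c, thr in enumerate(thresholds):
            ax = axes[r][c]
            sub = summary[(summary["mode"] == mode) & (summary["score_threshold"] == thr)]
            sub = sub.sort_values("read_length")
            x = np.arange(len(sub))
            ax.bar(x - 0.2, sub["precision"], width=0.4, color="tab:red", label="precision")
            ax.bar(x + 0.2, sub["recall"], width=0.4, color="tab:blue", label="recall")
            ax.set_xticks(x, [str(v) for v in sub["read_length"]])
            ax.set_ylim(0, 1.05)
            if r == 0:
                ax.set_title(f"score >= {thr}", fontsize=9)
            if c == 0:
                ax.set_ylabel(mode, fontsize=9)
    axes[0][0].legend(fontsize=7)
    fig.suptitle("precision/recall by read length")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
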