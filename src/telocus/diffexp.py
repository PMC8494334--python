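"""Per-timepoint differential expression of TE loci (and genes).

Mutant and wild-type samples are compared separately at each timepoint
(weeks 4, 8, 12, 17) with a deliberately small negative-binomial Wald
test: median-of-ratios size factors, a method-of-moments dispersion
floored at 0.01 and pooled across the two groups, and a delta-method
standard error for the log2 fold change.  This replicates the decision
rule of the full shrinkage-based NB machinery at desk scale, not its
internals.  Calls use the conventional cutoffs |log2FC| >= 2 and
adjusted p < 0.05 (Benjamini-Hochberg within each timepoint), and the
per-timepoint calls of each feature are summarized into a trajectory
pattern (constant / switch / transient / complex / none).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from telocus.synth import Sample

__all__ = [
    "DEResult",
    "normalize",
    "de_test",
    "call_de",
    "trajectory",
    "de_timecourse",
]

_LN2_SQ = float(np.log(2.0) ** 2)


@dataclass(slots=True)
class DEResult:
    feature_id: str
    timepoint: int
    log2fc: float
    pvalue: float
    padj: float
    call: str  # "up" | "down" | "ns"


def normalize(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized count matrix.

    ``counts`` is features x samples.  The size factor of a sample is
    the median, over features with nonzero counts in every sample, of
    the ratio of its count to the feature's geometric mean.
    """
    mat = counts.to_numpy(dtype=float)
    everywhere = (mat > 0).all(axis=1)
    if not everywhere.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; consider a "
            "pseudo-reference (add a pseudocount) before normalizing"
        )
    ref = mat[everywhere]
    log_gm = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = ref / np.exp(log_gm)
    sf = np.median(ratios, axis=0)
    size_factors = pd.Series(sf, index=counts.columns, name="size_factor")
    normalized = counts / sf
    return size_factors, normalized


def _group_stats(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return mat.mean(axis=1), mat.var(axis=1, ddof=1)


def de_test(
    normalized: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    dispersion_floor: float = 0.01,
) -> pd.DataFrame:
    """NB Wald test of group_a (e.g. MUT) vs group_b (e.g. WT).

    Returns a frame indexed like ``normalized`` with columns log2fc,
    pvalue, padj (BH across the tested features).  log2FC uses a 0.5
    pseudocount; features that are all-zero get p = 1.  The dispersion
    is estimated by method of moments and, because per-feature moments
    are hopeless with two replicates per group, pooled into a common
    dispersion across all features (clipped at zero, averaged, floored);
    the Wald statistic is referred to the normal distribution.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    a = normalized[list(group_a)].to_numpy(dtype=float)
    b = normalized[list(group_b)].to_numpy(dtype=float)
    ma, va = _group_stats(a)
    mb, vb = _group_stats(b)
    log2fc = np.log2((ma + 0.5) / (mb + 0.5))

    with np.errstate(divide="ignore", invalid="ignore"):
        da = np.where(ma > 0, (va - ma) / np.maximum(ma, 1e-12) ** 2, np.nan)
        db = np.where(mb > 0, (vb - mb) / np.maximum(mb, 1e-12) ** 2, np.nan)
    stacked = np.vstack([da, db])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN feature rows
        per_feature = np.nanmean(stacked, axis=0)
    if np.all(np.isnan(per_feature)):
        common = 0.0
    else:
        common = float(np.nanmean(np.clip(per_feature, 0.0, None)))
    disp = np.full(ma.shape, max(common, dispersion_floor))

    na, nb = a.shape[1], b.shape[1]
    var_a = (ma + disp * ma**2) / na
    var_b = (mb + disp * mb**2) / nb
    se2 = var_a / ((ma + 0.5) ** 2 * _LN2_SQ) + var_b / ((mb + 0.5) ** 2 * _LN2_SQ)
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(wald))
    allzero = (ma == 0) & (mb == 0)
    pvalue = np.where(allzero, 1.0, pvalue)
    log2fc = np.where(allzero, 0.0, log2fc)
    padj = multipletests(pvalue, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvalue, "padj": padj},
        index=normalized.index,
    )


def call_de(
    log2fc: float,
    padj: float,
    lfc_cut: float = 2.0,
    alpha: float = 0.05,
    strict_lfc: bool = False,
) -> str:
    """up / down / ns from the fold-change and adjusted-p cutoffs.

    ``strict_lfc`` switches |log2FC| >= cut (default) to a strict >.
    A missing (NaN) adjusted p yields ``ns``.
    """
    if padj is None or (isinstance(padj, float) and np.isnan(padj)):
        return "ns"
    if padj >= alpha:
        return "ns"
    if (log2fc > lfc_cut) if strict_lfc else (log2fc >= lfc_cut):
        return "up"
    if (log2fc < -lfc_cut) if strict_lfc else (log2fc <= -lfc_cut):
        return "down"
    return "ns"


def trajectory(calls: Sequence[str]) -> str:
    """Cross-timepoint expression pattern from per-timepoint calls.

    constant: the same non-ns call at >= 3 timepoints; switch: both up
    and down occur; transient: non-ns at exactly one timepoint; none:
    all ns; complex: anything else.
    """
    if len(calls) != 4:
        raise ValueError("expected calls for all 4 timepoints")
    bad = set(calls) - {"up", "down", "ns"}
    if bad:
        raise ValueError(f"unknown calls: {sorted(bad)}")
    n_up = calls.count("up")
    n_down = calls.count("down")
    if n_up and n_down:
        return "switch"
    if n_up >= 3 or n_down >= 3:
        return "constant"
    non_ns = n_up + n_down
    if non_ns == 0:
        return "none"
    if non_ns == 1:
        return "transient"
    return "complex"


def de_timecourse(
    counts: pd.DataFrame,
    samples: Sequence[Sample],
    lfc_cut: float = 2.0,
    alpha: float = 0.05,
    strict_lfc: bool = False,
) -> pd.DataFrame:
    """Per-timepoint MUT-vs-WT tests plus trajectory labels.

    ``counts`` is features x samples (raw); normalization is done once
    across all samples, testing and BH adjustment per timepoint.
    Returns a long frame (feature_id, timepoint, log2fc, pvalue, padj,
    call, trajectory).
    """
    by_name = {s.name: s for s in samples}
    missing = [c for c in counts.columns if c not in by_name]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    _, norm = normalize(counts)
    timepoints = sorted({s.timepoint for s in by_name.values()})
    frames = []
    for tp in timepoints:
        ga = [n for n, s in by_name.items() if s.timepoint == tp and s.condition == "MUT"]
        gb = [n for n, s in by_name.items() if s.timepoint == tp and s.condition == "WT"]
        res = de_test(norm, ga, gb)
        res.insert(0, "timepoint", tp)
        res["call"] = [
            call_de(l, p, lfc_cut=lfc_cut, alpha=alpha, strict_lfc=strict_lfc)
            for l, p in zip(res["log2fc"], res["padj"])
        ]
        frames.append(res)
    long = pd.concat(frames)
    long.index.name = "feature_id"
    long = long.reset_index()
    traj = (
        long.sort_values(["feature_id", "timepoint"])
        .groupby("feature_id")["call"]
        .apply(lambda c: trajectory(list(c)))
        .rename("trajectory")
    )
    return long.merge(traj, on="feature_id")
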