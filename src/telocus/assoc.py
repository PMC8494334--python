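"""Gene~TE expression association by per-pair linear modelling.

For each gene-TE pair produced by the context stage, gene expression is
modelled as a linear function of TE expression across all samples
(ordinary least squares on log2(1 + normalized counts)), the TE-term
p-values are Benjamini-Hochberg adjusted jointly across all pairs, and
the Pearson correlation coefficient is reported for the significant
pairs to give the association a sign: exonic TEs, being part of their
host gene's transcript, should correlate positively; negative intronic
correlations suggest transcriptional interference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from telocus.context import ContextLink

__all__ = ["AssociationResult", "LinearFit", "fit_linear", "associate_all", "log_expression"]


class LinearFit(NamedTuple):
    slope: float
    se: float
    t: float
    pvalue: float


@dataclass(slots=True)
class AssociationResult:
    gene_id: str
    te_id: str
    context: str
    slope: float
    slope_se: float
    pvalue: float
    padj: float
    pearson_r: float  # NaN unless padj < alpha
    n_samples: int


def fit_linear(
    gene_expr: Sequence[float],
    te_expr: Sequence[float],
    covariates: np.ndarray | None = None,
) -> LinearFit:
    """OLS of gene expression on TE expression (plus optional covariates).

    Returns the slope of the TE term with its standard error and
    two-sided t-test p-value.  Raises on constant TE expression or when
    there are fewer than 3 + n_covariates observations.
    """
    y = np.asarray(gene_expr, dtype=float)
    x = np.asarray(te_expr, dtype=float)
    n_cov = 0 if covariates is None else np.atleast_2d(covariates).shape[1]
    if y.shape != x.shape:
        raise ValueError("gene and TE expression must have equal length")
    if len(y) < 3 + n_cov:
        raise ValueError(f"need >= {3 + n_cov} samples, got {len(y)}")
    if np.ptp(x) == 0:
        raise ValueError("TE expression is constant; slope undefined")
    design = x[:, None]
    if covariates is not None:
        design = np.column_stack([design, covariates])
    design = sm.add_constant(design, prepend=False)
    fit = sm.OLS(y, design).fit()
    return LinearFit(
        slope=float(fit.params[0]),
        se=float(fit.bse[0]),
        t=float(fit.tvalues[0]),
        pvalue=float(fit.pvalues[0]),
    )


def log_expression(normalized: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilizing transform used on both genes and TEs."""
    return np.log2(1.0 + normalized)


def associate_all(
    pairs: Sequence[ContextLink],
    gene_expr: pd.DataFrame,
    te_expr: pd.DataFrame,
    alpha: float = 0.05,
    covariates: np.ndarray | None = None,
) -> list[AssociationResult]:
    """Fit every gene-TE pair, BH-adjust jointly, add Pearson r if significant.

    ``gene_expr`` and ``te_expr`` are log-scale expression matrices
    (features x samples) over the same sample columns.  Pairs whose TE
    expression is constant (e.g. never detected) are skipped.
    """
    if list(gene_expr.columns) != list(te_expr.columns):
        raise ValueError("gene and TE expression matrices must share sample columns")
    fits: list[tuple[ContextLink, LinearFit]] = []
    for link in pairs:
        if not link.gene_id or link.gene_id not in gene_expr.index:
            continue
        if link.te_id not in te_expr.index:
            continue
        y = gene_expr.loc[link.gene_id].to_numpy(dtype=float)
        x = te_expr.loc[link.te_id].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        fits.append((link, fit_linear(y, x, covariates=covariates)))
    if not fits:
        return []
    padj = multipletests([f.pvalue for _, f in fits], method="fdr_bh")[1]
    out = []
    n = gene_expr.shape[1]
    for (link, f), q in zip(fits, padj):
        r = np.nan
        if q < alpha:
            y = gene_expr.loc[link.gene_id].to_numpy(dtype=float)
            x = te_expr.loc[link.te_id].to_numpy(dtype=float)
            r = float(stats.pearsonr(x, y).statistic)
        out.append(
            AssociationResult(
                gene_id=link.gene_id,
                te_id=link.te_id,
                context=link.context,
                slope=f.slope,
                slope_se=f.se,
                pvalue=f.pvalue,
                padj=float(q),
                pearson_r=r,
                n_samples=n,
            )
        )
    return out
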