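"""Covariate residualization of expression and the cell-type association scan.

Covariate adjustment is ordinary least squares per gene: each gene's
expression vector is replaced by its residual on a design matrix of the
requested phenotype covariates (plus an intercept, always). Categorical
covariates are expanded to indicator columns; collinear columns are dropped
(and logged) before fitting, so residuals are exactly orthogonal to the
retained design.

The cell-type scan asks, per gene, whether the joint regression on the
blood cell-type proportions explains significant variance (F-test), and
reports the fraction of genes passing a Bonferroni-corrected threshold.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = ["build_design", "residualize", "cell_type_scan"]


def build_design(
    phen: PhenotypeTable, covariates: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Design matrix (with intercept) for the named covariates.

    ``"cells"`` expands to every ``cell_*`` proportion column; categorical
    columns expand to drop-first indicators. Collinear columns are dropped
    greedily (logged); raises if the result is still rank deficient.
    """
    df = phen.data
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    for name in covariates:
        if name == "cells":
            for c in phen.cell_prop_names:
                cols[c] = df[c].to_numpy(dtype=float)
            continue
        if name not in df.columns:
            raise KeyError(f"covariate {name!r} not in phenotype table")
        col = df[name]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy(dtype=float)
        else:
            cols[name] = col.to_numpy(dtype=float)

    names = list(cols)
    kept: list[str] = []
    x = np.empty((len(df), 0))
    for nm in names:
        cand = np.column_stack([x, cols[nm]])
        if np.linalg.matrix_rank(cand) > x.shape[1]:
            x = cand
            kept.append(nm)
        else:
            logger.info("dropping collinear design column %s", nm)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix rank deficient after drops")
    return x, kept


def residualize(
    expr: ExpressionMatrix, phen: PhenotypeTable, covariates: list[str]
) -> ExpressionMatrix:
    """Per-gene OLS residuals of expression on the covariate design.

    With an empty covariate list this is gene-mean centering. The returned
    matrix keeps the original gene and sample IDs.
    """
    if expr.sample_ids != phen.sample_ids:
        if set(expr.sample_ids) != set(phen.sample_ids):
            raise ValueError("sample mismatch between expression and phenotypes")
        phen = PhenotypeTable(phen.data.loc[expr.sample_ids].copy())
    x, _kept = build_design(phen, covariates)
    y = expr.values.T  # samples x genes
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return ExpressionMatrix(
        pd.DataFrame(resid.T, index=expr.gene_ids, columns=expr.sample_ids)
    )


def cell_type_scan(
    expr: ExpressionMatrix,
    phen: PhenotypeTable,
    cell_prop_names: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Per-gene F-test of the joint cell-proportion regression.

    Returns (table, fraction) where the table has one row per gene with the
    F statistic, p-value and Bonferroni call at ``alpha / n_genes``, and the
    fraction is the share of genes passing that threshold. Constant genes
    get p = 1 with a warning.
    """
    if expr.n_samples < 3:
        raise ValueError("need >= 3 samples for the cell-type scan")
    cell_prop_names = cell_prop_names or phen.cell_prop_names
    if not cell_prop_names:
        raise ValueError("no cell proportion columns")
    df = phen.data.loc[expr.sample_ids]

    x = np.column_stack(
        [np.ones(expr.n_samples)] + [df[c].to_numpy(dtype=float) for c in cell_prop_names]
    )
    rank = np.linalg.matrix_rank(x)
    df_model = rank - 1
    df_resid = expr.n_samples - rank
    if df_model < 1 or df_resid < 1:
        raise ValueError("degenerate cell-proportion design")

    y = expr.values.T
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    rss = ((y - x @ beta) ** 2).sum(axis=0)
    tss = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    constant = tss <= 1e-300
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant genes; p set to 1", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = ((tss - rss) / df_model) / (rss / df_resid)
    p = stats.f.sf(f, df_model, df_resid)
    p = np.where(constant | ~np.isfinite(f), 1.0, p)

    threshold = alpha / expr.n_genes
    table = pd.DataFrame(
        {"gene_id": expr.gene_ids, "f_stat": f, "p": p, "significant": p < threshold}
    )
    return table, float(table["significant"].mean())
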