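"""Single-gene trait association and the Bonferroni signature gene set.

Each gene's residualized expression is regressed against each blood-pressure
trait (SBP, DBP in mm Hg; hypertension as a 0/1 outcome in the same linear
score test). The test is a two-sided Pearson correlation t-test, which is
equivalent to the slope test of the simple regression trait ~ expression in
either direction. The signature set is the union of genes passing
Bonferroni correction (family alpha over the number of measured genes) for
any trait, with per-trait counts and sign tallies reported alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, PhenotypeTable

__all__ = ["associate_traits", "signature_set"]

TRAITS = ("sbp", "dbp", "htn")


def _pearson_columns(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each row of x with vector y, plus two-sided t-test p."""
    n = y.shape[0]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    return r, np.clip(p, np.finfo(float).tiny, 1.0)


def associate_traits(
    resid: ExpressionMatrix,
    phen: PhenotypeTable,
    traits: tuple[str, ...] = TRAITS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per gene x trait: regression beta, Pearson r, two-sided p, Bonferroni flag.

    Significance is p < alpha / n_genes (per trait). Constant traits are an
    error; the p-value is invariant under affine rescaling of trait units.
    """
    if resid.n_samples < 4:
        raise ValueError("need >= 4 samples")
    phen_df = phen.data.loc[resid.sample_ids]
    x = resid.values
    threshold = alpha / resid.n_genes
    frames = []
    for trait in traits:
        y = phen_df[trait].to_numpy(dtype=float)
        if np.std(y) == 0:
            raise ValueError(f"constant trait {trait!r}")
        r, p = _pearson_columns(x, y)
        # slope of trait ~ expression has the sign (and test) of r
        sx = x.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = r * y.std() / np.where(sx == 0, np.nan, sx)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": resid.gene_ids,
                    "trait": trait,
                    "beta": np.nan_to_num(beta, nan=0.0),
                    "r": r,
                    "p": p,
                    "bonferroni_significant": p < threshold,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def signature_set(assoc: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Union of Bonferroni-significant genes across traits, with tallies.

    Returns a dict with the gene list (sorted), per-trait significant
    counts, genes significant for every tested trait, and positive/negative
    direction counts (sign of r for the gene's most significant trait).
    """
    sig = assoc[assoc["bonferroni_significant"]]
    genes = sorted(set(sig["gene_id"]))
    per_trait = {
        t: int((sig["trait"] == t).sum()) for t in assoc["trait"].unique()
    }
    n_traits = assoc["trait"].nunique()
    counts = sig.groupby("gene_id")["trait"].nunique()
    all_traits = sorted(counts[counts == n_traits].index)

    pos = neg = 0
    for g in genes:
        rows = sig[sig["gene_id"] == g]
        best = rows.loc[rows["p"].idxmin()]
        if best["r"] >= 0:
            pos += 1
        else:
            neg += 1
    return {
        "genes": genes,
        "per_trait_counts": per_trait,
        "all_trait_genes": all_traits,
        "n_positive": pos,
        "n_negative": neg,
    }
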