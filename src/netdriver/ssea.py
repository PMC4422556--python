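"""SNP-set enrichment analysis (SSEA).

Tests whether the eSNPs of a gene set carry systematically smaller
trait-GWAS p-values than the background of all eSNPs. The chain is:
map the set's genes to their (cis and trans) eSNPs, collapse linkage
disequilibrium (greedy pruning at r2 >= 0.8, keeping the SNP with the best
eQTL p so selection never peeks at the GWAS outcome), then compare the
set's GWAS p-values against the identically pruned background with

* a one-sided two-sample Kolmogorov-Smirnov test (alternative: set
  p-values stochastically smaller), and
* a one-sided Fisher's exact test on the 2x2 table of (set vs background)
  x (GWAS p < 0.05 vs not).

Empirical calibration repeats the full chain on random gene sets of equal
size (permutation p = #{perm p < observed p} / n_perm, reported as
"<0.001" when no permutation beats the observed value). A set is called
genetically inferred causal when both analytic tests pass Bonferroni
correction over the number of sets tested, for at least one trait.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneSetCollection, LDMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "map_geneset_esnps",
    "ld_prune",
    "ks_enrichment",
    "fisher_enrichment",
    "permutation_calibrate",
    "ssea_run",
]


def map_geneset_esnps(gene_set: list[str], esnp: pd.DataFrame) -> list[str]:
    """Union of eSNPs (cis and trans) of the member genes, sorted.

    Genes with no eSNP contribute nothing (count logged).
    """
    members = set(gene_set)
    hit = esnp[esnp["gene_id"].isin(members)]
    n_missing = len(members - set(hit["gene_id"]))
    if n_missing:
        logger.info("%d of %d genes have no eSNP", n_missing, len(members))
    return sorted(set(hit["snp_id"]))


def ld_prune(
    snps: list[str],
    ld: LDMatrix,
    r2_threshold: float = 0.8,
    priority: dict[str, float] | None = None,
) -> list[str]:
    """Greedy LD clumping: keep the best remaining SNP, drop everything still
    unprocessed with r2 >= threshold to it.

    "Best" is the smallest ``priority`` value (eQTL p in the SSEA chain),
    ties broken lexicographically by SNP id, so the output is canonical and
    independent of input order. Pairs without LD information count as
    unlinked.
    """
    priority = priority or {}
    ordered = sorted(set(snps), key=lambda s: (priority.get(s, 0.0), s))
    sub = ld.submatrix(ordered)
    pos = {s: i for i, s in enumerate(ordered)}
    kept: list[str] = []
    dropped: set[str] = set()
    for s in ordered:
        if s in dropped:
            continue
        kept.append(s)
        linked = np.nonzero(sub[pos[s]] >= r2_threshold)[0]
        for j in linked:
            t = ordered[j]
            if t != s:
                dropped.add(t)
    return kept


def ks_enrichment(geneset_p: list[float], background_p: list[float]) -> float:
    """One-sided two-sample KS p: are the set's p-values stochastically
    smaller than the background's? Sets with < 5 SNPs are flagged low-power
    upstream but still computed."""
    if len(geneset_p) == 0 or len(background_p) == 0:
        raise ValueError("empty p-value list")
    # alternative="greater": ECDF of the first sample lies above the second,
    # i.e. the first sample's values are stochastically smaller
    res = stats.ks_2samp(geneset_p, background_p, alternative="greater")
    return float(res.pvalue)


def fisher_enrichment(
    geneset_p: list[float], background_p: list[float], gwas_alpha: float = 0.05
) -> float:
    """One-sided (greater) Fisher's exact test on (set vs background) x
    (GWAS p < gwas_alpha vs not)."""
    gs = np.asarray(geneset_p, dtype=float)
    bg = np.asarray(background_p, dtype=float)
    if gs.size == 0 or bg.size == 0:
        raise ValueError("empty p-value list")
    table = [
        [int((gs < gwas_alpha).sum()), int((gs >= gwas_alpha).sum())],
        [int((bg < gwas_alpha).sum()), int((bg >= gwas_alpha).sum())],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def _set_pvalues(
    gene_set: list[str],
    esnp: pd.DataFrame,
    gwas: pd.DataFrame,
    ld: LDMatrix,
    trait_col: str,
    r2_threshold: float,
    priority: dict[str, float],
) -> tuple[list[str], np.ndarray]:
    snps = map_geneset_esnps(gene_set, esnp)
    pruned = ld_prune(snps, ld, r2_threshold, priority)
    present = [s for s in pruned if s in gwas.index]
    return pruned, gwas.loc[present, trait_col].to_numpy(dtype=float)


def permutation_calibrate(
    gene_set: list[str],
    pool: list[str],
    esnp: pd.DataFrame,
    gwas: pd.DataFrame,
    ld: LDMatrix,
    trait_col: str,
    observed_ks: float,
    observed_fisher: float,
    background_p: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    r2_threshold: float = 0.8,
    gwas_alpha: float = 0.05,
    priority: dict[str, float] | None = None,
) -> tuple[float, float]:
    """Empirical p-values from random gene sets of equal size.

    Each permutation draws |set| genes without replacement from the pool of
    genes having >= 1 eSNP and reruns the full map -> prune -> test chain.
    Counts use strict inequality (ties do not beat the observed p).
    """
    size = len(set(gene_set))
    if len(pool) < size:
        raise ValueError("permutation pool smaller than the gene set")
    rng = np.random.default_rng(seed)
    pool_arr = np.asarray(sorted(set(pool)))
    priority = priority or {}
    beat_ks = beat_fisher = 0
    for _ in range(n_perm):
        draw = rng.choice(pool_arr, size=size, replace=False)
        _, perm_p = _set_pvalues(
            list(draw), esnp, gwas, ld, trait_col, r2_threshold, priority
        )
        if perm_p.size == 0:
            continue
        if ks_enrichment(perm_p, background_p) < observed_ks:
            beat_ks += 1
        if fisher_enrichment(perm_p, background_p, gwas_alpha) < observed_fisher:
            beat_fisher += 1
    return beat_ks / n_perm, beat_fisher / n_perm


def format_perm_p(p: float, n_perm: int) -> str:
    """Zero beats are reported as '< 1/n_perm' (the "<0.001" convention)."""
    return f"<{1 / n_perm:g}" if p == 0 else f"{p:g}"


def ssea_run(
    gene_sets: GeneSetCollection,
    esnp: pd.DataFrame,
    gwas: pd.DataFrame,
    ld: LDMatrix,
    traits: tuple[str, ...] = ("sbp", "dbp"),
    alpha: float = 0.05,
    r2_threshold: float = 0.8,
    gwas_alpha: float = 0.05,
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Run both SSEA tests for every gene set x trait.

    Bonferroni correction multiplies analytic p-values by the number of gene
    sets tested. ``causal_call`` is per set: both corrected analytic tests
    below ``alpha`` for at least one trait. Set ``n_perm > 0`` to add
    permutation-calibrated empirical p columns.
    """
    n_sets = len(gene_sets)
    if n_sets == 0:
        raise ValueError("no gene sets")
    # best (smallest) eQTL p per SNP: the pruning priority
    priority = esnp.groupby("snp_id")["eqtl_p"].min().to_dict()
    all_snps = sorted(set(esnp["snp_id"]))
    background_pruned = ld_prune(all_snps, ld, r2_threshold, priority)
    bg_present = [s for s in background_pruned if s in gwas.index]
    pool = sorted(set(esnp["gene_id"]))

    rows = []
    for set_name, members in gene_sets.items():
        raw_snps = map_geneset_esnps(members, esnp)
        for trait in traits:
            trait_col = f"p_{trait}"
            if trait_col not in gwas.columns:
                raise KeyError(f"GWAS table lacks column {trait_col}")
            bg_p = gwas.loc[bg_present, trait_col].to_numpy(dtype=float)
            pruned, set_p = _set_pvalues(
                members, esnp, gwas, ld, trait_col, r2_threshold, priority
            )
            row = {
                "gene_set": set_name,
                "trait": trait,
                "n_esnps_raw": len(raw_snps),
                "n_esnps_pruned": len(pruned),
                "low_power": 0 < len(set_p) < 5,
                "status": "ok" if len(set_p) else "no_esnps",
            }
            if len(set_p) == 0:
                row.update(p_ks=np.nan, p_fisher=np.nan)
            else:
                row["p_ks"] = ks_enrichment(set_p, bg_p)
                row["p_fisher"] = fisher_enrichment(set_p, bg_p, gwas_alpha)
                if n_perm > 0:
                    import zlib

                    sub_seed = zlib.crc32(f"{set_name}|{trait}|{seed}".encode()) % (2**31)
                    perm_ks, perm_fisher = permutation_calibrate(
                        members, pool, esnp, gwas, ld, trait_col,
                        row["p_ks"], row["p_fisher"], bg_p,
                        n_perm=n_perm, seed=sub_seed,
                        r2_threshold=r2_threshold, gwas_alpha=gwas_alpha,
                        priority=priority,
                    )
                    row["perm_p_ks"] = perm_ks
                    row["perm_p_fisher"] = perm_fisher
                    row["perm_p_ks_str"] = format_perm_p(perm_ks, n_perm)
                    row["perm_p_fisher_str"] = format_perm_p(perm_fisher, n_perm)
            rows.append(row)
    out = pd.DataFrame(rows)
    out["p_ks_corrected"] = np.minimum(out["p_ks"] * n_sets, 1.0)
    out["p_fisher_corrected"] = np.minimum(out["p_fisher"] * n_sets, 1.0)
    out["both_significant"] = (
        (out["p_ks_corrected"] < alpha) & (out["p_fisher_corrected"] < alpha)
    ).fillna(False)
    causal = out.groupby("gene_set")["both_significant"].any()
    out["causal_call"] = out["gene_set"].map(causal)
    return out
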