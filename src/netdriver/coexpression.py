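"""Weighted gene coexpression network analysis.

Builds an unsigned weighted network from Pearson gene-gene correlations
(adjacency a_ij = |r_ij|^beta), selects the soft-thresholding power beta by
the scale-free topology fit, computes the topological overlap matrix

    w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu * a_uj,   k_i = sum_{u != i} a_iu,

clusters genes by average-linkage hierarchical clustering on 1 - TOM with a
dynamic branch cut, summarises each module by its eigengene (first principal
component of the standardized member submatrix), and relates modules to
traits, to the single-gene signature, and to modules from a second network.

Module labels are drawn from a fixed color vocabulary ordered by decreasing
module size; unassigned genes are "grey".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .enrich_stats import EnrichmentResult, overlap_test
from .io_formats import ExpressionMatrix, PhenotypeTable

__all__ = [
    "COLOR_LIST",
    "ScaleFreeFit",
    "CoexpressionNetwork",
    "ModulePartition",
    "pick_soft_power",
    "build_network",
    "tom_from_adjacency",
    "detect_modules",
    "eigengenes",
    "module_trait",
    "module_signature_enrichment",
    "module_overlap",
]

# WGCNA-style color vocabulary, assigned by size rank; "grey" is reserved
COLOR_LIST = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "chocolate",
    "sienna", "yellowgreen", "lightsteelblue", "navajowhite", "plum",
]
GREY = "grey"


@dataclass
class ScaleFreeFit:
    """Scale-free topology fit across candidate soft powers.

    ``records`` has one row per power: beta, fit_r2 (signed: negative when
    the log-log slope is positive, so only a declining p(k) counts as
    scale-free), slope, mean connectivity. ``power`` is the selected beta.
    """

    records: pd.DataFrame
    power: int
    passed: bool


@dataclass
class CoexpressionNetwork:
    gene_ids: list[str]
    adjacency: np.ndarray  # |r|^beta, unit diagonal
    tom: np.ndarray  # topological overlap, unit diagonal
    power: int


@dataclass
class ModulePartition:
    """gene -> module color labels plus (optional) eigengene summaries."""

    labels: dict[str, str]
    eigengene_matrix: pd.DataFrame | None = None  # modules x samples, unit norm rows
    variance_explained: dict[str, float] = field(default_factory=dict)

    @property
    def modules(self) -> list[str]:
        sizes: dict[str, int] = {}
        for m in self.labels.values():
            if m != GREY:
                sizes[m] = sizes.get(m, 0) + 1
        return sorted(sizes, key=lambda m: (-sizes[m], m))

    def members(self, module: str) -> list[str]:
        return [g for g, m in self.labels.items() if m == module]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.labels), "module": list(self.labels.values())}
        )


# ---------------------------------------------------------------------------
# Network construction


def _abs_corr(resid: ExpressionMatrix) -> np.ndarray:
    x = resid.values
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(resid.gene_ids, sd) if s == 0]
        raise ValueError(f"zero-variance genes: {bad[:5]}")
    r = np.corrcoef(x)
    return np.clip(np.abs(r), 0.0, 1.0)


def _scale_free_r2(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """Signed fit index and slope of log10 p(k) ~ log10 k over occupied bins."""
    k = k[k > 0]
    if k.size < 3 or np.allclose(k, k[0]):
        return 0.0, 0.0
    counts, edges = np.histogram(k, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = (counts > 0) & (centers > 0)
    if keep.sum() < 3:
        return 0.0, 0.0
    lx = np.log10(centers[keep])
    ly = np.log10(counts[keep] / counts.sum())
    slope, _icpt, r, _p, _se = stats.linregress(lx, ly)
    r2 = float(r**2)
    return (r2 if slope < 0 else -r2), float(slope)


def pick_soft_power(
    resid: ExpressionMatrix,
    powers: range = range(1, 21),
    r2_threshold: float = 0.8,
    n_bins: int = 10,
) -> ScaleFreeFit:
    """Select the smallest soft power whose connectivity distribution fits a
    scale-free law (signed R^2 > threshold); falls back to the argmax power
    with a warning when none passes."""
    if resid.n_genes < 30:
        raise ValueError("need >= 30 genes for a scale-free fit")
    absr = _abs_corr(resid)
    rows = []
    for beta in powers:
        a = absr**beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        r2, slope = _scale_free_r2(k, n_bins)
        rows.append({"beta": int(beta), "fit_r2": r2, "slope": slope, "mean_k": float(k.mean())})
    records = pd.DataFrame(rows)
    passing = records[records["fit_r2"] > r2_threshold]
    if len(passing):
        power = int(passing["beta"].iloc[0])
        passed = True
    else:
        power = int(records.loc[records["fit_r2"].idxmax(), "beta"])
        passed = False
        warnings.warn(
            f"no power reached fit R2 > {r2_threshold}; using argmax beta={power}",
            stacklevel=2,
        )
    return ScaleFreeFit(records=records, power=power, passed=passed)


def tom_from_adjacency(a: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap with the min-connectivity denominator."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # with zero diagonal, l_ij = sum_{u != i,j} a_iu a_uj
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (l + a) / denom
    w = np.nan_to_num(w, nan=0.0)
    np.fill_diagonal(w, 1.0)
    return np.clip(w, 0.0, 1.0)


def build_network(resid: ExpressionMatrix, power: int) -> CoexpressionNetwork:
    if power < 1:
        raise ValueError("power must be >= 1")
    absr = _abs_corr(resid)
    a = absr ** float(power)
    tom = tom_from_adjacency(a)
    np.fill_diagonal(a, 1.0)
    return CoexpressionNetwork(gene_ids=resid.gene_ids, adjacency=a, tom=tom, power=int(power))


# ---------------------------------------------------------------------------
# Module detection


def _cut(node, height: float):
    """Branches of the dendrogram whose top merge is at or below ``height``."""
    if node.is_leaf() or node.dist <= height:
        return [node]
    return _cut(node.left, height) + _cut(node.right, height)


def _select_cut_height(heights: np.ndarray, frac: float) -> float:
    """Branch-cut height for a TOM dendrogram.

    Soft thresholding acts multiplicatively, so at higher powers every
    dissimilarity compresses toward 1 and a fixed fraction of the maximum
    merge height lands inside real branches. The cut is therefore placed in
    the largest gap of -log10(1 - h) (a multiplicative scale) among the
    upper half of merge heights; when no clear gap exists (unstructured
    data) it falls back to ``frac`` times the maximum height.
    """
    hs = np.sort(heights)
    static = frac * hs[-1]
    u = -np.log10(np.clip(1.0 - hs, 1e-15, None))
    lo = len(hs) // 2
    tail = u[lo:]
    if len(tail) < 3:
        return static
    gaps = np.diff(tail)
    gi = int(np.argmax(gaps))
    # require the gap to dominate its neighborhood, else fall back
    if gaps[gi] < 0.5:
        return static
    u_cut = 0.5 * (tail[gi] + tail[gi + 1])
    return 1.0 - 10.0 ** (-u_cut)


def _deep_split(node, min_size: int):
    """Recursively split a branch at its root merge while both children are
    large enough to stand as modules on their own."""
    if (
        node.is_leaf()
        or node.left.get_count() < min_size
        or node.right.get_count() < min_size
    ):
        return [node]
    return _deep_split(node.left, min_size) + _deep_split(node.right, min_size)


def detect_modules(
    net: CoexpressionNetwork,
    min_size: int = 30,
    cut_height_frac: float = 0.99,
    deep_split: bool = True,
) -> ModulePartition:
    """Average-linkage clustering on 1 - TOM with a dynamic branch cut.

    The dendrogram is cut at ``cut_height_frac`` times the maximum merge
    height; each branch of size >= min_size becomes a module (optionally
    re-split at its internal root merges while both halves stay >= min_size);
    leftover genes go to grey. Labels come from the color vocabulary in
    decreasing size order.
    """
    n = len(net.gene_ids)
    if min_size > n:
        raise ValueError("min_size exceeds the number of genes")
    dissim = 1.0 - net.tom
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    root = to_tree(z)
    height = _select_cut_height(z[:, 2], cut_height_frac)

    branches = _cut(root, height)
    clusters = []
    for b in branches:
        if deep_split:
            clusters.extend(_deep_split(b, min_size))
        else:
            clusters.append(b)

    sized = [c for c in clusters if c.get_count() >= min_size]
    sized.sort(key=lambda c: (-c.get_count(), min(c.pre_order(lambda x: x.id))))
    if len(sized) > len(COLOR_LIST):
        raise ValueError("more modules than color labels; increase min_size")

    labels = {g: GREY for g in net.gene_ids}
    for color, cl in zip(COLOR_LIST, sized):
        for leaf in cl.pre_order(lambda x: x.id):
            labels[net.gene_ids[leaf]] = color
    return ModulePartition(labels=labels)


def eigengenes(
    resid: ExpressionMatrix, partition: ModulePartition
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Module eigengenes: first right singular vector of the gene-standardized
    member submatrix, unit norm, sign-oriented so the mean correlation with
    member genes is non-negative. variance_explained is s1^2 / sum(s^2)."""
    rows, var_exp = {}, {}
    data = resid.data
    for module in partition.modules:
        members = partition.members(module)
        sub = data.loc[members].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=0)
        if (sd == 0).any():
            raise ValueError(f"zero-variance gene in module {module}")
        zmat = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        u, s, vt = np.linalg.svd(zmat, full_matrices=False)
        eig = vt[0]
        if u[:, 0].mean() < 0:  # orient toward the members
            eig = -eig
        rows[module] = eig
        var_exp[module] = float(s[0] ** 2 / (s**2).sum())
    mat = pd.DataFrame(rows, index=resid.sample_ids).T
    partition.eigengene_matrix = mat
    partition.variance_explained = var_exp
    return mat, var_exp


# ---------------------------------------------------------------------------
# Module-level association tests


def module_trait(
    eigengene_matrix: pd.DataFrame,
    phen: PhenotypeTable,
    traits: tuple[str, ...] = ("sbp", "dbp"),
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each trait.

    Two-sided t-test p per module x trait, Benjamini-Hochberg FDR across all
    pairs, and tier flags at p < 0.05, FDR < 0.2 and FDR < 0.05. A module's
    headline association is its minimum p over traits (``min_p_module``
    column repeats it on each of the module's rows).
    """
    phen_df = phen.data.loc[eigengene_matrix.columns]
    rows = []
    for module, eig in eigengene_matrix.iterrows():
        for trait in traits:
            r, p = stats.pearsonr(eig.to_numpy(), phen_df[trait].to_numpy(dtype=float))
            rows.append({"module": module, "trait": trait, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["sig_p05"] = out["p"] < 0.05
    out["sig_fdr20"] = out["fdr"] < 0.2
    out["sig_fdr05"] = out["fdr"] < 0.05
    out["min_p_module"] = out.groupby("module")["p"].transform("min")
    return out


def module_signature_enrichment(
    partition: ModulePartition, signature: list[str]
) -> list[EnrichmentResult]:
    """One-sided Fisher test of module membership x signature membership.

    The universe is every partitioned gene (grey genes included in the
    universe but not in any module)."""
    universe = set(partition.labels)
    sig = set(signature) & universe
    results = []
    for module in partition.modules:
        members = set(partition.members(module))
        k = len(members & sig)
        res = EnrichmentResult(
            k=k, n=len(members), K=len(sig), N=len(universe),
            p=overlap_test(k, len(members), len(sig), len(universe)),
            name=module, overlap_genes=sorted(members & sig),
        )
        results.append(res)
    m = max(len(results), 1)
    for r in results:
        r.p_corrected = min(1.0, r.p * m)
    return results


def module_overlap(
    part_a: ModulePartition, part_b: ModulePartition, alpha: float = 0.05
) -> dict:
    """Cross-network module correspondence by pairwise Fisher overlap.

    Bonferroni over all module pairs; a module pair is "conserved" when it is
    significant and each is the other's best match (reciprocal). A module of
    A significantly matching >= 2 modules of B is reported as split.
    """
    universe = sorted(set(part_a.labels) & set(part_b.labels))
    uni = set(universe)
    mods_a, mods_b = part_a.modules, part_b.modules
    n_pairs = max(len(mods_a) * len(mods_b), 1)
    rows = []
    for ma in mods_a:
        set_a = set(part_a.members(ma)) & uni
        for mb in mods_b:
            set_b = set(part_b.members(mb)) & uni
            k = len(set_a & set_b)
            p = overlap_test(k, len(set_a), len(set_b), len(uni)) if set_a and set_b else 1.0
            rows.append(
                {
                    "module_a": ma, "module_b": mb, "k": k,
                    "n_a": len(set_a), "n_b": len(set_b),
                    "p": p, "p_corrected": min(1.0, p * n_pairs),
                }
            )
    table = pd.DataFrame(rows)
    sig = table[table["p_corrected"] < alpha]

    conserved = []
    for ma in mods_a:
        rows_a = table[table["module_a"] == ma]
        best_b = rows_a.loc[rows_a["p"].idxmin(), "module_b"]
        rows_b = table[table["module_b"] == best_b]
        best_a = rows_b.loc[rows_b["p"].idxmin(), "module_a"]
        is_sig = bool(
            sig[(sig["module_a"] == ma) & (sig["module_b"] == best_b)].shape[0]
        )
        if is_sig and best_a == ma:
            conserved.append((ma, best_b))

    splits = {
        ma: sorted(grp["module_b"])
        for ma, grp in sig.groupby("module_a")
        if len(grp) >= 2
    }
    return {"table": table, "conserved": conserved, "splits": splits}
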