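"""Key-driver (KD) analysis on molecular interaction networks.

A key driver of a trait-associated gene set is a network node whose local
neighborhood — the union of its 1st-, 2nd- and 3rd-layer neighbors — is
significantly enriched for members of the gene set (one-sided Fisher /
hypergeometric test over all network nodes excluding the candidate).
Candidates are every node in the gene set's 3rd-layer expanding network
(the union of <=3-step neighborhoods of the set members present in the
network), and the Bonferroni correction count is the size of that candidate
pool. Directed networks are expanded ignoring edge direction by default.

Because neighborhoods of nearby nodes overlap heavily, raw significant
calls come in clumps around each true hub; ``filter_local_peaks`` keeps the
strongest call per neighborhood clump for reporting.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .enrich_stats import overlap_test
from .io_formats import MolecularNetwork

__all__ = [
    "neighborhood",
    "kd_test",
    "kd_scan",
    "filter_local_peaks",
    "replicate_kds",
    "rank_kds",
]


def _expansion_graph(net: MolecularNetwork, downstream_only: bool = False):
    if net.directed and not downstream_only:
        return net.graph.to_undirected(as_view=True)
    return net.graph


def neighborhood(
    net: MolecularNetwork, node: str, depth: int = 3, downstream_only: bool = False
) -> set[str]:
    """All nodes within graph distance <= depth of ``node``, excluding it."""
    g = _expansion_graph(net, downstream_only)
    if node not in g:
        raise KeyError(f"node {node!r} not in network {net.name}")
    reach = nx.single_source_shortest_path_length(g, node, cutoff=depth)
    return set(reach) - {node}


def kd_test(
    net: MolecularNetwork, node: str, gene_set: set[str], depth: int = 3
) -> tuple[int, float]:
    """Overlap count and one-sided enrichment p of the node's neighborhood
    with the gene set; universe = all network nodes except the candidate."""
    hood = neighborhood(net, node, depth)
    universe = net.nodes - {node}
    members = set(gene_set) & universe
    k = len(hood & members)
    p = overlap_test(k, len(hood), len(members), len(universe)) if hood else 1.0
    return k, p


def kd_scan(
    net: MolecularNetwork,
    gene_set: list[str],
    alpha: float = 0.05,
    depth: int = 3,
    correction: str = "pool",
) -> pd.DataFrame:
    """Test every candidate in the gene set's 3rd-layer expanding network.

    ``correction="pool"`` uses m = |candidate pool| (the expanding network of
    the tested set); ``"all_nodes"`` uses every network node. Returns all
    candidates sorted by kd_p with ``significant`` flags; rows are the
    KD records (gene, neighborhood size, overlap, p, corrected p).
    """
    members = set(gene_set) & net.nodes
    if not members:
        raise ValueError("gene set does not intersect the network")
    pool: set[str] = set(members)
    for gene in members:
        pool |= neighborhood(net, gene, depth)
    m = len(pool) if correction == "pool" else len(net.nodes)

    rows = []
    for cand in sorted(pool):
        hood = neighborhood(net, cand, depth)
        k, p = kd_test(net, cand, members, depth)
        rows.append(
            {
                "gene": cand,
                "network": net.name,
                "neighborhood_size": len(hood),
                "overlap_count": k,
                "kd_p": p,
                "kd_p_corrected": min(1.0, p * m),
            }
        )
    out = pd.DataFrame(rows).sort_values(["kd_p", "gene"]).reset_index(drop=True)
    out["significant"] = out["kd_p_corrected"] < alpha
    return out


def filter_local_peaks(
    kds: pd.DataFrame, net: MolecularNetwork, depth: int = 3
) -> pd.DataFrame:
    """Collapse clumps of overlapping significant KDs to their local peaks.

    Two candidates at graph distance <= 2 * depth have overlapping
    depth-limited neighborhoods and therefore restate the same enriched
    region. Walk significant candidates in ascending kd_p order and keep one
    only if its neighborhood is disjoint from every already-kept KD's —
    reporting one driver per enriched region.
    """
    g = _expansion_graph(net)
    sig = kds[kds["significant"]].sort_values(["kd_p", "gene"])
    radius = 2 * depth
    kept: list[str] = []
    kept_balls: list[set[str]] = []
    for gene in sig["gene"]:
        overlapping = False
        for ball in kept_balls:
            if gene in ball:
                overlapping = True
                break
        if not overlapping:
            kept.append(gene)
            kept_balls.append(
                set(nx.single_source_shortest_path_length(g, gene, cutoff=radius))
            )
    return sig[sig["gene"].isin(kept)].reset_index(drop=True)


def replicate_kds(
    kds_from_a: pd.DataFrame,
    net_b: MolecularNetwork,
    gene_set: list[str],
    alpha: float = 0.05,
    depth: int = 3,
) -> tuple[float, pd.DataFrame]:
    """Replication of network-A KDs in network B for the same gene set.

    A KD replicates iff it is a node of B and Bonferroni-significant there.
    Returns (replicated / testable, per-KD flag table); the fraction is NaN
    when no KD is testable in B.
    """
    scan_b = kd_scan(net_b, gene_set, alpha=alpha, depth=depth)
    sig_b = set(scan_b.loc[scan_b["significant"], "gene"])
    rows = []
    for gene in kds_from_a.loc[kds_from_a["significant"], "gene"]:
        testable = gene in net_b.nodes
        rows.append(
            {
                "gene": gene,
                "testable": testable,
                "replicated": bool(testable and gene in sig_b),
            }
        )
    flags = pd.DataFrame(rows, columns=["gene", "testable", "replicated"])
    n_testable = int(flags["testable"].sum())
    frac = float(flags["replicated"].sum() / n_testable) if n_testable else float("nan")
    return frac, flags


def rank_kds(
    kds: pd.DataFrame,
    esnp: pd.DataFrame,
    gwas: pd.DataFrame,
    twas: pd.DataFrame,
    g_thresh: float = 1e-5,
    t_alpha: float = 0.05,
) -> pd.DataFrame:
    """Tiered ranking of significant KDs.

    Tier GWAS: KDs whose own eSNPs reach GWAS p < g_thresh (minimum over
    the KD's eSNPs and traits), sorted by that p. Tier TWAS: remaining KDs
    with transcriptome-wide Bonferroni-significant trait association
    (minimum p over traits < t_alpha / n_genes), sorted by TWAS p. Tier
    MULTI: remaining KDs significant in >= 2 networks, sorted by kd_p.
    Everything else: tier OTHER, sorted by kd_p. Global rank follows tier
    order then within-tier order.
    """
    sig = kds[kds["significant"]].copy()
    if sig.empty:
        return sig.assign(tier=pd.Series(dtype=str), rank=pd.Series(dtype=int))
    p_cols = [c for c in gwas.columns if c.startswith("p_")]
    snp_min = gwas[p_cols].min(axis=1)

    def min_esnp_gwas_p(gene: str) -> float:
        snps = esnp.loc[esnp["gene_id"] == gene, "snp_id"]
        vals = snp_min.reindex(snps).dropna()
        return float(vals.min()) if len(vals) else np.nan

    n_genes = twas["gene_id"].nunique()
    twas_min = twas.groupby("gene_id")["p"].min()
    twas_cut = t_alpha / max(n_genes, 1)

    records = []
    nets_per_gene = kds[kds["significant"]].groupby("gene")["network"].nunique()
    for gene, grp in sig.groupby("gene"):
        best = grp.loc[grp["kd_p"].idxmin()]
        gp = min_esnp_gwas_p(gene)
        tp = float(twas_min.get(gene, np.nan))
        if np.isfinite(gp) and gp < g_thresh:
            tier, key = "GWAS", gp
        elif np.isfinite(tp) and tp < twas_cut:
            tier, key = "TWAS", tp
        elif nets_per_gene.get(gene, 0) >= 2:
            tier, key = "MULTI", best["kd_p"]
        else:
            tier, key = "OTHER", best["kd_p"]
        records.append(
            {
                "gene": gene,
                "network": best["network"],
                "kd_p": best["kd_p"],
                "kd_p_corrected": best["kd_p_corrected"],
                "min_esnp_gwas_p": gp,
                "twas_p": tp,
                "tier": tier,
                "sort_key": key,
            }
        )
    out = pd.DataFrame(records)
    tier_order = {"GWAS": 0, "TWAS": 1, "MULTI": 2, "OTHER": 3}
    out["tier_order"] = out["tier"].map(tier_order)
    out = out.sort_values(["tier_order", "sort_key", "gene"]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out.drop(columns=["tier_order", "sort_key"])
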