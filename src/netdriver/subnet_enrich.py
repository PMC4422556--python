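"""Key-driver-centered subnetworks and their enrichment tests.

Two subnetwork flavours: a *genetic* subnetwork (star of all genes whose
expression a SNP associates with, edges labelled cis/trans) and an
*interaction* subnetwork (induced subgraph on a key driver plus its <=3-step
neighborhood). Subnetwork gene lists are tested against literature gene
lists, GO-style term annotations and cross-species knockout DE signatures
with the shared hypergeometric overlap statistic; universes are always
explicit inputs, never inferred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .enrich_stats import EnrichmentResult, overlap_test
from .io_formats import MolecularNetwork
from .keydrivers import neighborhood

logger = logging.getLogger(__name__)

__all__ = [
    "Subnetwork",
    "genetic_subnetwork",
    "interaction_subnetwork",
    "set_enrichment",
    "mouse_overlap",
    "annotation_enrichment",
]


@dataclass
class Subnetwork:
    """A star (genetic) or induced (interaction) subnetwork around a center.

    ``roles`` labels each node by membership in the supplied candidate gene
    sets: "signature", "causal-module", "both" or "other".
    """

    center: str
    kind: str  # "genetic" | "interaction"
    nodes: list[str]
    edges: list[tuple[str, str, str]]  # (source, target, label)
    roles: dict[str, str] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return [n for n in self.nodes if n != self.center or self.kind == "interaction"]


def _role(gene: str, signature: set[str], causal: set[str]) -> str:
    in_sig, in_mod = gene in signature, gene in causal
    if in_sig and in_mod:
        return "both"
    if in_sig:
        return "signature"
    if in_mod:
        return "causal-module"
    return "other"


def genetic_subnetwork(
    snp_id: str,
    esnp: pd.DataFrame,
    signature: list[str] | None = None,
    causal_genes: list[str] | None = None,
) -> Subnetwork:
    """Star of every gene the SNP is an eSNP for, edges labelled cis/trans."""
    hits = esnp[esnp["snp_id"] == snp_id]
    if hits.empty:
        raise KeyError(f"SNP {snp_id!r} absent from the eSNP table")
    sig, mod = set(signature or []), set(causal_genes or [])
    nodes = [snp_id] + sorted(hits["gene_id"])
    edges = [
        (snp_id, gene, kind)
        for gene, kind in sorted(zip(hits["gene_id"], hits["kind"]))
    ]
    roles = {g: _role(g, sig, mod) for g in hits["gene_id"]}
    roles[snp_id] = "center"
    return Subnetwork(center=snp_id, kind="genetic", nodes=nodes, edges=edges, roles=roles)


def interaction_subnetwork(
    net: MolecularNetwork,
    kd: str,
    depth: int = 3,
    signature: list[str] | None = None,
    causal_genes: list[str] | None = None,
) -> Subnetwork:
    """Induced subgraph on the KD plus its <= depth neighborhood."""
    hood = neighborhood(net, kd, depth)
    node_set = hood | {kd}
    sub = net.graph.subgraph(node_set)
    sig, mod = set(signature or []), set(causal_genes or [])
    edges = [(a, b, "") for a, b in sorted(sub.edges())]
    roles = {g: _role(g, sig, mod) for g in node_set}
    roles[kd] = "center"
    return Subnetwork(
        center=kd, kind="interaction", nodes=sorted(node_set), edges=edges, roles=roles
    )


def set_enrichment(
    query: list[str], reference: list[str], universe: list[str]
) -> EnrichmentResult:
    """Hypergeometric upper-tail enrichment of query in reference over universe.

    Genes outside the universe are dropped from both sets (count logged).
    fold = (k/n)/(K/N).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query) & uni
    ref = set(reference) & uni
    n_dropped = len(set(query) - uni) + len(set(reference) - uni)
    if n_dropped:
        logger.info("dropped %d genes outside the universe", n_dropped)
    if not q:
        raise ValueError("query empty after intersecting with the universe")
    k = len(q & ref)
    return EnrichmentResult(
        k=k, n=len(q), K=len(ref), N=len(uni),
        p=overlap_test(k, len(q), len(ref), len(uni)),
        overlap_genes=sorted(q & ref),
    )


def mouse_overlap(
    subnet: Subnetwork,
    mouse_de: pd.DataFrame,
    orthologs: dict[str, str],
    universe: list[str],
    q_threshold: float = 0.05,
) -> EnrichmentResult:
    """Overlap of subnetwork genes with knockout DE genes mapped to human.

    DE calls are mouse genes at q < 0.05, translated through the 1:1
    ortholog map; direction of change is ignored.
    """
    de_mouse = mouse_de.loc[mouse_de["q_value"] < q_threshold, "mouse_gene_id"]
    de_human = [orthologs[m] for m in de_mouse if m in orthologs]
    if not de_human:
        raise ValueError("no mappable DE genes")
    if subnet.kind == "interaction":
        genes = subnet.nodes  # the KD itself is a gene
    else:
        genes = [n for n in subnet.nodes if n != subnet.center]  # drop the SNP
    return set_enrichment(genes, de_human, universe)


def annotation_enrichment(
    query: list[str],
    annotations: dict[str, list[str]],
    universe: list[str],
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term one-sided Fisher enrichment, Bonferroni over all terms.

    The per-term significance threshold is ``family_alpha / n_terms``
    (0.05 / 825 ~= 6e-5 for a full GO biological-process table).
    """
    uni = set(universe)
    q = set(query) & uni
    if not uni or not q:
        raise ValueError("empty universe or query after intersection")
    n_terms = len(annotations)
    threshold = family_alpha / n_terms
    rows = []
    for term in sorted(annotations):
        ref = set(annotations[term]) & uni
        k = len(q & ref)
        p = overlap_test(k, len(q), len(ref), len(uni)) if ref else 1.0
        rows.append(
            {
                "term_id": term,
                "k": k,
                "n": len(q),
                "K": len(ref),
                "N": len(uni),
                "fold": (k / len(q)) / (len(ref) / len(uni)) if ref else 0.0,
                "p": p,
                "p_corrected": min(1.0, p * n_terms),
                "significant": p < threshold,
            }
        )
    return pd.DataFrame(rows)
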