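"""End-to-end orchestration: residualize -> single-gene associations ->
coexpression modules -> SNP-set enrichment -> key drivers -> subnetworks.

Stages communicate via files in a run directory so any stage can be
inspected or re-run; a JSON summary collects per-stage counts and the seed.
Inputs can either be supplied as paths or simulated in place from a
``SimulationConfig`` (the default study conditions).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import coexpression as cx
from . import diffexpr, keydrivers, preprocess, ssea, subnet_enrich
from .io_formats import (
    GeneSetCollection,
    compute_ld,
    read_dosages,
    read_esnp,
    read_expression,
    read_gwas,
    read_mouse_de,
    read_network,
    read_orthologs,
    read_phenotypes,
    write_expression,
    write_gmt,
)
from .synthetic_data import SimulationConfig, write_simulation

__all__ = ["PipelineConfig", "run_pipeline", "report"]


@dataclass
class PipelineConfig:
    """Paths, stage toggles and thresholds for a full run."""

    seed: int
    input_dir: str | None = None  # directory holding the standard input TSVs
    simulate: SimulationConfig | None = None  # generate inputs instead
    adjust_cell_types: bool = True
    covariates: tuple[str, ...] = ("age", "sex", "bmi", "cells", "cohort")
    gene_alpha: float = 0.05
    esnp_fdr: float = 0.1
    ld_r2: float = 0.8
    gwas_dichotomy: float = 0.05
    n_perm: int = 0
    kd_alpha: float = 0.05
    kd_depth: int = 3
    gwas_tier_threshold: float = 1e-5
    min_module_size: int = 30
    soft_power: int | None = None  # None = auto-select
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.input_dir is None and self.simulate is None:
            raise ValueError("either input_dir or simulate must be given")


def _covariates(cfg: PipelineConfig) -> list[str]:
    covs = list(cfg.covariates)
    if not cfg.adjust_cell_types and "cells" in covs:
        covs.remove("cells")
    return covs


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute every stage in order; writes stage outputs and summary.json.

    Returns the summary dict (also written to ``outdir/summary.json``).
    Every output is reproducible from the config and seed.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs
    if cfg.simulate is not None:
        indir = out / "inputs"
        write_simulation(cfg.simulate, indir)
    else:
        indir = Path(cfg.input_dir)
    expr = read_expression(indir / "expression.tsv")
    phen = read_phenotypes(indir / "phenotypes.tsv")
    esnp = read_esnp(indir / "esnp.tsv", fdr_threshold=cfg.esnp_fdr)
    gwas = read_gwas(indir / "gwas.tsv")
    ld = compute_ld(read_dosages(indir / "dosages.tsv"))
    network = read_network(indir / "network.tsv", name="network")

    summary: dict = {"seed": cfg.seed, "n_genes": expr.n_genes, "n_samples": expr.n_samples}

    # --- preprocess
    resid = preprocess.residualize(expr, phen, _covariates(cfg))
    write_expression(resid, out / "residuals.tsv")
    scan, cell_frac = preprocess.cell_type_scan(expr, phen)
    scan.to_csv(out / "cell_type_scan.tsv", sep="\t", index=False)
    summary["cell_type_significant_fraction"] = round(cell_frac, 4)

    # --- single-gene associations and signature
    assoc = diffexpr.associate_traits(resid, phen, alpha=cfg.gene_alpha)
    assoc.to_csv(out / "trait_associations.tsv", sep="\t", index=False)
    signature = diffexpr.signature_set(assoc, alpha=cfg.gene_alpha)
    summary["signature_size"] = len(signature["genes"])
    summary["signature_per_trait"] = signature["per_trait_counts"]

    # --- coexpression modules
    if cfg.soft_power is None:
        fit = cx.pick_soft_power(resid)
        power = fit.power
        fit.records.to_csv(out / "scale_free_fit.tsv", sep="\t", index=False)
    else:
        power = cfg.soft_power
    net = cx.build_network(resid, power)
    partition = cx.detect_modules(net, min_size=cfg.min_module_size)
    partition.to_frame().to_csv(out / "modules.tsv", sep="\t", index=False)
    eig, var_exp = cx.eigengenes(resid, partition)
    eig.to_csv(out / "eigengenes.tsv", sep="\t", index_label="module")
    mt = cx.module_trait(eig, phen)
    mt.to_csv(out / "module_trait.tsv", sep="\t", index=False)
    summary["soft_power"] = int(power)
    summary["module_count"] = len(partition.modules)
    summary["modules_trait_p05"] = sorted(set(mt.loc[mt["sig_p05"], "module"]))

    # --- SSEA over signature + modules
    sets: dict[str, list[str]] = {}
    if signature["genes"]:
        sets["signature"] = signature["genes"]
    for module in partition.modules:
        sets[module] = partition.members(module)
    collection = GeneSetCollection(sets, {k: "" for k in sets})
    write_gmt(collection, out / "gene_sets.gmt")
    ssea_table = ssea.ssea_run(
        collection, esnp, gwas, ld,
        alpha=cfg.gene_alpha, r2_threshold=cfg.ld_r2,
        gwas_alpha=cfg.gwas_dichotomy, n_perm=cfg.n_perm, seed=cfg.seed,
    )
    ssea_table.to_csv(out / "ssea.tsv", sep="\t", index=False)
    causal_modules = sorted(
        set(ssea_table.loc[ssea_table["causal_call"], "gene_set"]) - {"signature"}
    )
    summary["n_gene_sets_tested"] = len(collection)
    summary["causal_modules"] = causal_modules

    # --- key drivers on the genetically inferred causal gene set
    causal_genes = sorted({g for m in causal_modules for g in partition.members(m)})
    summary["n_causal_genes"] = len(causal_genes)
    if causal_genes and set(causal_genes) & network.nodes:
        kds = keydrivers.kd_scan(
            network, causal_genes, alpha=cfg.kd_alpha, depth=cfg.kd_depth
        )
        kds.to_csv(out / "kd_scan.tsv", sep="\t", index=False)
        peaks = keydrivers.filter_local_peaks(kds, network, depth=cfg.kd_depth)
        ranked = keydrivers.rank_kds(
            peaks.assign(significant=True), esnp, gwas, assoc,
            g_thresh=cfg.gwas_tier_threshold, t_alpha=cfg.gene_alpha,
        )
        ranked.to_csv(out / "kd_ranked.tsv", sep="\t", index=False)
        summary["kd_count"] = {network.name: int(kds["significant"].sum())}
        summary["reported_kds"] = ranked["gene"].tolist()
        summary["top_kd"] = ranked["gene"].iloc[0] if len(ranked) else None
        summary["tier1_kds"] = ranked.loc[ranked["tier"] == "GWAS", "gene"].tolist()
    else:
        kds = ranked = None
        summary["kd_count"] = {network.name: 0}
        summary["reported_kds"] = []
        summary["top_kd"] = None
        summary["tier1_kds"] = []

    # --- subnetwork around the top KD + cross-species overlap
    mouse_path = indir / "mouse_de.tsv"
    if summary["top_kd"] is not None:
        sub = subnet_enrich.interaction_subnetwork(
            network, summary["top_kd"], depth=cfg.kd_depth,
            signature=signature["genes"], causal_genes=causal_genes,
        )
        pd.DataFrame(sub.edges, columns=["source", "target", "label"]).to_csv(
            out / "subnetwork_edges.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {"node": sub.nodes, "role": [sub.roles[n] for n in sub.nodes]}
        ).to_csv(out / "subnetwork_nodes.tsv", sep="\t", index=False)
        summary["subnetwork_size"] = len(sub.nodes)
        if mouse_path.exists():
            mouse = read_mouse_de(mouse_path)
            orthologs = read_orthologs(indir / "orthologs.tsv")
            res = subnet_enrich.mouse_overlap(
                sub, mouse, orthologs, universe=sorted(network.nodes)
            )
            summary["mouse_overlap"] = {
                "k": res.k, "n": res.n, "K": res.K, "N": res.N,
                "fold": round(res.fold, 3), "p": res.p,
            }

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def report(run_dir) -> str:
    """Human-readable markdown report regenerated from a run directory."""
    run = Path(run_dir)
    lines = ["# Pipeline report", ""]
    summary_path = run / "summary.json"
    if summary_path.exists():
        summary = json.loads(summary_path.read_text())
        lines += [
            f"- samples: {summary.get('n_samples')}, genes: {summary.get('n_genes')}",
            f"- signature genes: {summary.get('signature_size')}",
            f"- coexpression modules: {summary.get('module_count')}",
            f"- genetically inferred causal modules: {', '.join(summary.get('causal_modules', [])) or 'none'}",
            "",
        ]
    else:
        lines.append("_summary absent_")

    ssea_path = run / "ssea.tsv"
    lines.append("## SNP-set enrichment")
    if ssea_path.exists():
        t = pd.read_csv(ssea_path, sep="\t")
        cols = [c for c in ["gene_set", "trait", "n_esnps_pruned", "p_ks", "p_fisher",
                            "perm_p_ks_str", "perm_p_fisher_str", "causal_call"] if c in t.columns]
        lines.append(t[cols].to_markdown(index=False))
    else:
        lines.append("_section absent_")
    lines.append("")

    kd_path = run / "kd_ranked.tsv"
    lines.append("## Key drivers")
    if kd_path.exists():
        t = pd.read_csv(kd_path, sep="\t")
        if len(t):
            lines.append(t.to_markdown(index=False))
        else:
            lines.append("No key drivers found.")
    else:
        lines.append("_section absent_")
    lines.append("")

    lines.append("## Cross-species overlap")
    if summary_path.exists() and "mouse_overlap" in json.loads(summary_path.read_text()):
        mo = json.loads(summary_path.read_text())["mouse_overlap"]
        lines.append(
            f"{mo['k']}/{mo['n']} subnetwork genes overlap the knockout DE set "
            f"({mo['K']}/{mo['N']} in the universe): fold {mo['fold']}, p = {mo['p']:.3g}"
        )
    else:
        lines.append("_section absent_")
    text = "\n".join(lines) + "\n"
    (run / "report.md").write_text(text)
    return text
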