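"""Synthetic multi-omic data with planted ground truth.

Generates every input the pipeline consumes — an expression matrix with
planted coexpression modules, blood-pressure-like traits partially driven by
the module factors, an eSNP map whose causal-module eSNPs carry inflated
GWAS association, block-LD genotype dosages, a scale-free interaction
network with planted key-driver hubs, and a knockout-style mouse DE list
concentrated in a chosen hub's neighborhood — so every downstream stage has
a parameter-recovery test with no external download.

The expression model is a Gaussian factor model: for gene g in module m,

    x_gi = sqrt(rho_m) * f_mi + sum_c beta_gc z_ci + sqrt(1 - rho_m) * eps_gi

where f_m ~ N(0,1) is the module factor and rho_m the within-module
correlation target. Traits are linear in the module factors and covariates,
scaled to mm Hg; hypertension is thresholded at SBP >= 140 or DBP >= 90.

A single global seed is expanded into per-stage substreams (counter-based
SeedSequence keys) so each stage regenerates independently and
deterministically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    MolecularNetwork,
    PhenotypeTable,
    write_expression,
    write_gmt,
    write_network,
    write_phenotypes,
)

__all__ = [
    "ModuleSpec",
    "NetworkSpec",
    "MouseDESpec",
    "SimulationConfig",
    "GroundTruth",
    "gen_expression",
    "gen_genetics",
    "gen_network",
    "gen_mouse_de",
    "simulate_all",
    "write_simulation",
]

# stage ids for substream derivation
_STAGE_EXPRESSION = 1
_STAGE_GENETICS = 2
_STAGE_NETWORK = 3
_STAGE_MOUSE = 4


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class ModuleSpec:
    name: str
    size: int
    within_corr: float = 0.6
    trait_effect: float = 0.1


@dataclass
class NetworkSpec:
    n_nodes: int = 1500
    attachment_k: int = 1
    planted_kd_count: int = 2
    kd_neighborhood_enrichment: float = 0.7
    kd_hub_degree: int = 40  # leaves attached to each planted hub


@dataclass
class MouseDESpec:
    target_kd: str | None = None  # default: first planted KD
    perturb_fraction: float = 0.4
    background_fraction: float = 0.15


@dataclass
class SimulationConfig:
    """All knobs of the generator. ``seed`` is mandatory."""

    seed: int
    n_samples: int = 200
    n_genes: int = 500
    modules: list[ModuleSpec] = field(
        default_factory=lambda: [
            ModuleSpec(f"mod{i + 1}", 50) for i in range(6)
        ]
    )
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.15, "sex": 0.15, "bmi": 0.15, "cohort": 0.15, "cell": 0.3,
        }
    )
    trait_covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.3, "sex": 0.1, "bmi": 0.25, "cohort": 0.05}
    )
    dbp_sbp_corr: float = 0.6
    n_snps: int = 1500
    ld_block_size: int = 3
    n_ld_samples: int = 400
    maf_range: tuple[float, float] = (0.1, 0.5)
    esnps_per_gene: int = 2
    causal_modules: list[str] = field(
        default_factory=lambda: ["mod1", "mod2", "mod3", "mod4"]
    )
    gwas_noncentrality: float = 30.0
    network: NetworkSpec = field(default_factory=NetworkSpec)
    mouse_de: MouseDESpec = field(default_factory=MouseDESpec)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ConfigError("module sizes sum exceeds n_genes")
        for m in self.modules:
            if not 0 < m.within_corr <= 0.99:
                raise ConfigError(
                    f"infeasible within-correlation target {m.within_corr} for {m.name}"
                )
        names = [m.name for m in self.modules]
        unknown = set(self.causal_modules) - set(names)
        if unknown:
            raise ConfigError(f"causal_modules not in module list: {sorted(unknown)}")
        if self.esnps_per_gene > self.ld_block_size:
            raise ConfigError("more eSNPs per gene requested than SNPs per LD block")
        if self.esnps_per_gene > self.n_snps:
            raise ConfigError("more eSNPs requested than SNPs")
        for frac in (
            self.network.kd_neighborhood_enrichment,
            self.mouse_de.perturb_fraction,
            self.mouse_de.background_fraction,
        ):
            if not 0 <= frac <= 1:
                raise ConfigError(f"fraction {frac} outside [0, 1]")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stage]))


@dataclass
class GroundTruth:
    """Planted structure, for recovery tests against emitted files."""

    true_partition: dict[str, str | None] = field(default_factory=dict)
    true_trait_loadings: dict[str, float] = field(default_factory=dict)
    true_causal_modules: list[str] = field(default_factory=list)
    true_kds: list[str] = field(default_factory=list)
    true_perturbed_genes: list[str] = field(default_factory=list)
    # in-memory extras (not serialized): module factors, samples x modules
    factors: pd.DataFrame | None = None

    def module_genes(self, name: str) -> list[str]:
        return [g for g, m in self.true_partition.items() if m == name]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("factors")
        return json.dumps(d, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------


def gen_expression(cfg: SimulationConfig) -> tuple[ExpressionMatrix, PhenotypeTable, GroundTruth]:
    """Factor-model expression, phenotypes and the planted partition."""
    rng = cfg.rng(_STAGE_EXPRESSION)
    n, g = cfg.n_samples, cfg.n_genes

    gene_ids = [f"G{i:04d}" for i in range(g)]
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # covariates
    age = rng.normal(51, 10, n)
    sex = rng.binomial(1, 0.45, n).astype(float)
    bmi = rng.normal(27, 5, n)
    cohort = rng.binomial(1, 0.7, n)  # 1 = third-generation-like
    cells = rng.dirichlet([10.0, 6.0, 4.0], size=n)  # three major cell types
    cell_names = ["cell_neutrophil", "cell_lymphocyte", "cell_monocyte"]

    def z(v):
        return (v - v.mean()) / v.std()

    zcov = {
        "age": z(age), "sex": z(sex), "bmi": z(bmi), "cohort": z(cohort.astype(float)),
        "cell": z(cells[:, 0]),  # dominant cell fraction drives expression
    }

    truth = GroundTruth()
    factors = {}
    x = np.empty((g, n))
    idx = 0
    for mod in cfg.modules:
        f = rng.standard_normal(n)
        factors[mod.name] = f
        lam = np.sqrt(mod.within_corr)
        for _ in range(mod.size):
            gid = gene_ids[idx]
            truth.true_partition[gid] = mod.name
            eps = rng.standard_normal(n)
            row = lam * f + np.sqrt(1 - mod.within_corr) * eps
            for cname, effect in cfg.covariate_effects.items():
                row = row + rng.normal(0, effect) * zcov[cname]
            x[idx] = row + rng.normal(7, 1)
            idx += 1
    while idx < g:  # null genes: pure noise + covariates
        gid = gene_ids[idx]
        truth.true_partition[gid] = None
        row = rng.standard_normal(n)
        for cname, effect in cfg.covariate_effects.items():
            row = row + rng.normal(0, effect) * zcov[cname]
        x[idx] = row + rng.normal(7, 1)
        idx += 1

    # traits: sbp_z = sum_m a_m f_m + covariate part + noise, Var ~= 1,
    # so a module's trait_effect is (approximately) its factor-SBP correlation
    a = {m.name: m.trait_effect for m in cfg.modules}
    b = dict(cfg.trait_covariate_effects)
    sys_var = sum(v**2 for v in a.values()) + sum(v**2 for v in b.values())
    if sys_var >= 1:
        raise ConfigError("trait effects + covariate effects exceed unit variance")
    sbp_z = sum(a[m] * factors[m] for m in a) + sum(b[c] * zcov[c] for c in b)
    sbp_z = sbp_z + np.sqrt(1 - sys_var) * rng.standard_normal(n)
    rho = cfg.dbp_sbp_corr
    dbp_z = rho * sbp_z + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    sbp = 118 + 14 * sbp_z
    dbp = 74 + 9 * dbp_z

    phen = pd.DataFrame(
        {
            "sbp": sbp, "dbp": dbp, "age": age, "sex": sex.astype(int), "bmi": bmi,
            "cohort": np.where(cohort == 1, "gen3", "offspring"),
            **{cn: cells[:, i] for i, cn in enumerate(cell_names)},
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    truth.true_trait_loadings = dict(a)
    truth.true_causal_modules = list(cfg.causal_modules)
    truth.factors = pd.DataFrame(factors, index=sample_ids)

    expr = ExpressionMatrix(pd.DataFrame(x, index=gene_ids, columns=sample_ids))
    return expr, PhenotypeTable(phen), truth


def gen_genetics(
    cfg: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """eSNP table, GWAS summary statistics and genotype dosages.

    SNPs come in LD blocks (copy-with-flip-noise, within-block r2 >= ~0.8).
    Each gene's eSNPs live in one block; genes occupy distinct blocks while
    blocks last (round-robin afterwards). GWAS p-values for eSNPs of
    causal-module genes are drawn from a noncentral chi-square (1 df) tail;
    every other SNP is Uniform(0,1).
    """
    rng = cfg.rng(_STAGE_GENETICS)
    n_blocks = cfg.n_snps // cfg.ld_block_size
    if n_blocks == 0:
        raise ConfigError("n_snps smaller than one LD block")
    snp_ids = [f"RS{i:06d}" for i in range(cfg.n_snps)]

    # dosages: block seed SNP + noisy copies
    flip = 0.05  # per-sample redraw probability for block copies
    dos = np.empty((cfg.n_ld_samples, cfg.n_snps), dtype=float)
    for bi in range(n_blocks):
        maf = rng.uniform(*cfg.maf_range)
        seed_col = rng.binomial(2, maf, cfg.n_ld_samples).astype(float)
        for j in range(cfg.ld_block_size):
            col = bi * cfg.ld_block_size + j
            if j == 0:
                dos[:, col] = seed_col
            else:
                redraw = rng.random(cfg.n_ld_samples) < flip
                copy = seed_col.copy()
                copy[redraw] = rng.binomial(2, maf, int(redraw.sum()))
                dos[:, col] = copy
    rest = n_blocks * cfg.ld_block_size
    for col in range(rest, cfg.n_snps):  # leftover SNPs: independent
        dos[:, col] = rng.binomial(2, rng.uniform(*cfg.maf_range), cfg.n_ld_samples)
    dosages = pd.DataFrame(dos, index=[f"I{i:04d}" for i in range(cfg.n_ld_samples)],
                           columns=snp_ids)

    # eSNP table
    genes = list(truth.true_partition)
    records = []
    for gi, gene in enumerate(genes):
        block = gi % n_blocks
        base = block * cfg.ld_block_size
        offs = rng.permutation(cfg.ld_block_size)[: cfg.esnps_per_gene]
        for k, off in enumerate(sorted(offs)):
            records.append(
                {
                    "snp_id": snp_ids[base + off],
                    "gene_id": gene,
                    "kind": "cis" if k == 0 else "trans",
                    "eqtl_p": 10.0 ** -rng.uniform(3, 12),
                    "eqtl_fdr": rng.uniform(0, 0.1),
                }
            )
    esnp = pd.DataFrame.from_records(records).drop_duplicates(["snp_id", "gene_id"])
    esnp = esnp.reset_index(drop=True)

    # GWAS: inflate eSNPs of causal-module genes
    causal_genes = {
        g for g, m in truth.true_partition.items() if m in set(truth.true_causal_modules)
    }
    causal_snps = set(esnp.loc[esnp["gene_id"].isin(causal_genes), "snp_id"])
    nc = cfg.gwas_noncentrality
    p_cols = {}
    for trait in ("sbp", "dbp"):
        p = rng.uniform(size=cfg.n_snps)
        if nc > 0 and causal_snps:
            mask = np.array([s in causal_snps for s in snp_ids])
            stat = stats.ncx2.rvs(df=1, nc=nc, size=int(mask.sum()), random_state=rng)
            p[mask] = np.clip(stats.chi2.sf(stat, df=1), 1e-300, 1.0)
        p_cols[f"p_{trait}"] = p
    gwas = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chr": [f"chr{(i // cfg.ld_block_size) % 22 + 1}" for i in range(cfg.n_snps)],
            "pos": np.arange(1, cfg.n_snps + 1) * 1000,
            **p_cols,
        }
    ).set_index("snp_id")
    return esnp, gwas, dosages


def gen_network(cfg: SimulationConfig, truth: GroundTruth) -> MolecularNetwork:
    """Preferential-attachment graph with planted key-driver hubs.

    Planted KDs are high-degree nodes placed far apart; their <=3-step
    neighborhoods are filled with causal-module genes at rate
    ``kd_neighborhood_enrichment``; all remaining node labels are assigned
    randomly from the leftover gene pool plus filler symbols.
    """
    rng = cfg.rng(_STAGE_NETWORK)
    spec = cfg.network
    n_hub_nodes = spec.planted_kd_count * (spec.kd_hub_degree + 1)
    n_main = spec.n_nodes - n_hub_nodes
    if n_main < 10:
        raise ConfigError("n_nodes too small for the requested planted hubs")
    g0 = nx.barabasi_albert_graph(n_main, spec.attachment_k, seed=int(rng.integers(2**31)))

    # planted hubs: stars of kd_hub_degree leaves, each hub tethered to a
    # peripheral (low-degree) node; tether points kept pairwise far apart so
    # each hub's 3-ball is a distinct, bounded signal region
    periph = sorted(g0.nodes, key=lambda v: (g0.degree[v], v))
    tethers: list[int] = []
    for v in periph:
        if len(tethers) >= spec.planted_kd_count:
            break
        if all(
            not nx.has_path(g0, v, t) or nx.shortest_path_length(g0, v, t) > 6
            for t in tethers
        ):
            tethers.append(v)
    if len(tethers) < spec.planted_kd_count:
        raise ConfigError("could not place planted hubs far enough apart")

    planted: list[int] = []
    nid = n_main
    for t in tethers:
        hub = nid
        nid += 1
        g0.add_edge(hub, t)
        for _ in range(spec.kd_hub_degree):
            g0.add_edge(hub, nid)
            nid += 1
        planted.append(hub)

    # ball nodes ordered closest-first so enrichment concentrates on the hub
    balls = {}
    for p in planted:
        dist = nx.single_source_shortest_path_length(g0, p, cutoff=3)
        del dist[p]
        balls[p] = [v for v, _d in sorted(dist.items(), key=lambda kv: (kv[1], kv[0]))]

    causal_pool = [
        g for g, m in truth.true_partition.items() if m in set(truth.true_causal_modules)
    ]
    rng.shuffle(causal_pool)
    other_genes = [g for g in truth.true_partition if g not in set(causal_pool)]
    rng.shuffle(other_genes)
    filler = [f"N{i:05d}" for i in range(spec.n_nodes)]
    background = other_genes + filler

    # split the causal pool across hubs so each ball gets its own supply
    n_planted = max(len(planted), 1)
    chunk = len(causal_pool) // n_planted
    chunks = [causal_pool[i * chunk : (i + 1) * chunk] for i in range(n_planted)]
    leftover = causal_pool[n_planted * chunk :]

    labels: dict[int, str] = {}
    bi = 0
    for p, pool in zip(planted, chunks):
        ci = 0
        if ci < len(pool):  # the hub itself carries a causal-module gene
            labels[p] = pool[ci]
            ci += 1
        for node in balls[p]:
            if node in labels:
                continue
            if ci < len(pool) and rng.random() < spec.kd_neighborhood_enrichment:
                labels[node] = pool[ci]
                ci += 1
            else:
                labels[node] = background[bi]
                bi += 1
        leftover.extend(pool[ci:])

    remaining_pool = leftover + background[bi:]
    rng.shuffle(remaining_pool)
    ri = 0
    for node in g0.nodes:
        if node not in labels:
            labels[node] = remaining_pool[ri]
            ri += 1

    g = nx.relabel_nodes(g0, labels)
    truth.true_kds = [labels[p] for p in planted]
    return MolecularNetwork(name="synthetic_ppi", graph=g, directed=False)


def gen_mouse_de(
    cfg: SimulationConfig, truth: GroundTruth, network: MolecularNetwork
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Knockout-style DE list concentrated in the target KD's neighborhood.

    Orthologs are human symbols with first-letter capitalisation (1:1 by
    construction). DE calls are Bernoulli(perturb_fraction) inside the target
    KD's 3-layer neighborhood and Bernoulli(background_fraction) elsewhere;
    q-values are consistent with the calls (DE iff q < 0.05).
    """
    from .keydrivers import neighborhood

    rng = cfg.rng(_STAGE_MOUSE)
    spec = cfg.mouse_de
    target = spec.target_kd or (truth.true_kds[0] if truth.true_kds else None)
    if target is None or target not in network.nodes:
        raise ConfigError("mouse DE target KD not present in the network")

    ball = neighborhood(network, target, depth=3) | {target}
    measured = sorted(network.nodes)
    orthologs = {h.capitalize(): h for h in measured}  # mouse -> human

    records = []
    perturbed = []
    for human in measured:
        inside = human in ball
        p_de = spec.perturb_fraction if inside else spec.background_fraction
        is_de = rng.random() < p_de
        q = rng.uniform(0, 0.05) if is_de else rng.uniform(0.05, 1.0)
        records.append(
            {
                "mouse_gene_id": human.capitalize(),
                "q_value": q,
                "direction": int(rng.choice([-1, 1])),
            }
        )
        if is_de:
            perturbed.append(human)
    truth.true_perturbed_genes = perturbed
    return pd.DataFrame.from_records(records), orthologs


# ---------------------------------------------------------------------------


def simulate_all(cfg: SimulationConfig):
    """Run all four generator stages; returns a dict of artifacts + truth."""
    expr, phen, truth = gen_expression(cfg)
    esnp, gwas, dosages = gen_genetics(cfg, truth)
    network = gen_network(cfg, truth)
    mouse_de, orthologs = gen_mouse_de(cfg, truth, network)
    return {
        "expression": expr,
        "phenotypes": phen,
        "esnp": esnp,
        "gwas": gwas,
        "dosages": dosages,
        "network": network,
        "mouse_de": mouse_de,
        "orthologs": orthologs,
        "truth": truth,
    }


def write_simulation(cfg: SimulationConfig, outdir) -> dict:
    """Write every simulated input as TSV/GMT plus truth.json; returns artifacts."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    art = simulate_all(cfg)
    write_expression(art["expression"], out / "expression.tsv")
    write_phenotypes(art["phenotypes"], out / "phenotypes.tsv")
    art["esnp"].to_csv(out / "esnp.tsv", sep="\t", index=False)
    art["gwas"].to_csv(out / "gwas.tsv", sep="\t", index=True)
    art["dosages"].to_csv(out / "dosages.tsv", sep="\t", index_label="sample_id")
    write_network(art["network"], out / "network.tsv")
    art["mouse_de"].to_csv(out / "mouse_de.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"mouse_gene_id": list(art["orthologs"]), "human_gene_id": list(art["orthologs"].values())}
    ).to_csv(out / "orthologs.tsv", sep="\t", index=False)
    truth: GroundTruth = art["truth"]
    (out / "truth.json").write_text(truth.to_json())
    sets = {
        m.name: truth.module_genes(m.name) for m in cfg.modules
    }
    write_gmt(GeneSetCollection(sets, {k: "planted module" for k in sets}), out / "true_modules.gmt")
    return art
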