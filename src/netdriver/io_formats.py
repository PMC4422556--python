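"""Readers and writers for the tabular and graph formats the pipeline consumes.

Everything on disk is plain text: tab-separated tables with mandatory header
rows, GMT gene-set files (Broad dialect) and two/three-column edge lists.
Gene identity is the symbol string; every loader applies a single uppercase
normalisation pass so that symbols from different sources (expression arrays,
PPI databases, ortholog maps) join case-insensitively afterwards.

Positions are 1-based. No binary formats are read or written.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "PhenotypeTable",
    "MolecularNetwork",
    "GeneSetCollection",
    "LDMatrix",
    "read_expression",
    "write_expression",
    "read_phenotypes",
    "write_phenotypes",
    "read_esnp",
    "read_gwas",
    "read_dosages",
    "compute_ld",
    "read_ld_pairs",
    "read_network",
    "write_network",
    "read_gmt",
    "write_gmt",
    "read_annotations",
    "read_mouse_de",
    "read_orthologs",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _norm_symbol(s: str) -> str:
    return str(s).strip().upper()


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of (log-scale) expression values.

    ``data`` is indexed by gene symbol with sample identifiers as columns.
    Invariants enforced at construction: unique gene and sample IDs, fully
    numeric values, no missing entries.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene IDs: {dups[:5]}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dups[:5]}")
        if self.data.isna().any().any():
            raise FormatError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_expression(path, missing_policy: str = "reject") -> ExpressionMatrix:
    """Load a genes-x-samples TSV (first column gene IDs, header sample IDs).

    ``missing_policy``: ``"reject"`` fails on any missing/non-numeric cell;
    ``"drop_gene"`` drops genes with missing values (count logged).
    """
    if missing_policy not in ("reject", "drop_gene"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = [_norm_symbol(g) for g in df.index]
    if pd.Index(df.index).duplicated().any():
        dup = pd.Index(df.index)[pd.Index(df.index).duplicated()][0]
        raise FormatError(f"duplicate gene row: {dup}")
    try:
        num = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric expression value in {path}: {exc}") from exc
    if num.isna().any().any():
        if missing_policy == "reject":
            bad = num.index[num.isna().any(axis=1)].tolist()
            raise FormatError(f"missing values for genes {bad[:5]} under policy 'reject'")
        n_before = num.shape[0]
        num = num.dropna(axis=0)
        logger.info("dropped %d genes with missing values", n_before - num.shape[0])
    logger.info("loaded expression matrix: %d genes x %d samples", *num.shape)
    return ExpressionMatrix(num)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Phenotypes


@dataclass
class PhenotypeTable:
    """Per-sample phenotypes and covariates.

    Required columns: ``sbp``/``dbp`` (mm Hg), ``age``, ``sex`` (0/1),
    ``bmi``, ``cohort`` (categorical) and one or more ``cell_*`` proportion
    columns in [0, 1]. ``htn`` is the hypertension flag, derived as
    SBP >= 140 mm Hg or DBP >= 90 mm Hg when not supplied.
    """

    data: pd.DataFrame

    REQUIRED = ("sbp", "dbp", "age", "sex", "bmi", "cohort")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"phenotype table missing columns: {missing}")
        if df.index.duplicated().any():
            raise FormatError("duplicate sample IDs in phenotype table")
        if "htn" not in df.columns:
            df["htn"] = ((df["sbp"] >= 140) | (df["dbp"] >= 90)).astype(int)
        else:
            derived = ((df["sbp"] >= 140) | (df["dbp"] >= 90)).astype(int)
            if not (df["htn"].astype(int) == derived).all():
                raise FormatError("htn flag inconsistent with SBP>=140 / DBP>=90 rule")
        for c in self.cell_prop_names:
            v = df[c].astype(float)
            if (v < 0).any() or (v > 1).any():
                raise FormatError(f"cell proportion column {c} outside [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def cell_prop_names(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("cell_")]


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return PhenotypeTable(df)


def write_phenotypes(phen: PhenotypeTable, path) -> None:
    phen.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# eSNPs / GWAS / LD


def read_esnp(path, fdr_threshold: float | None = None) -> pd.DataFrame:
    """Load an eSNP table: snp_id, gene_id, kind (cis|trans), eqtl_p, eqtl_fdr.

    ``fdr_threshold`` optionally keeps only associations at eqtl_fdr below it
    (the upstream eQTL convention is FDR < 0.1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene_id": str})
    required = {"snp_id", "gene_id", "kind", "eqtl_p", "eqtl_fdr"}
    if not required.issubset(df.columns):
        raise FormatError(f"eSNP table missing columns: {sorted(required - set(df.columns))}")
    df["gene_id"] = df["gene_id"].map(_norm_symbol)
    bad_kind = set(df["kind"]) - {"cis", "trans"}
    if bad_kind:
        raise FormatError(f"eSNP kind must be cis|trans, got {sorted(bad_kind)}")
    if df.duplicated(["snp_id", "gene_id"]).any():
        raise FormatError("duplicate (snp_id, gene_id) pairs in eSNP table")
    if ((df["eqtl_p"] <= 0) | (df["eqtl_p"] > 1)).any():
        raise FormatError("eqtl_p outside (0, 1]")
    if fdr_threshold is not None:
        df = df[df["eqtl_fdr"] < fdr_threshold].reset_index(drop=True)
    return df


def read_gwas(path) -> pd.DataFrame:
    """Load GWAS summary statistics: snp_id, chr, pos and p_<trait> columns."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    if "snp_id" not in df.columns:
        raise FormatError("GWAS table missing snp_id column")
    p_cols = [c for c in df.columns if c.startswith("p_")]
    if not p_cols:
        raise FormatError("GWAS table has no p_<trait> columns")
    if df["snp_id"].duplicated().any():
        raise FormatError("duplicate snp_id in GWAS table")
    for c in p_cols:
        if ((df[c] <= 0) | (df[c] > 1)).any():
            raise FormatError(f"GWAS p-values in {c} outside (0, 1]")
    return df.set_index("snp_id")


class LDMatrix:
    """Pairwise LD (r-squared) between SNPs.

    Backed by a symmetric DataFrame with unit diagonal. Pairs absent from a
    pairwise input file are treated as unlinked (r2 = 0).
    """

    def __init__(self, r2: pd.DataFrame):
        if not r2.index.equals(r2.columns):
            raise FormatError("LD matrix index/columns mismatch")
        a = r2.to_numpy(dtype=float)
        if not np.allclose(a, a.T, atol=1e-12):
            raise FormatError("LD matrix not symmetric")
        np.fill_diagonal(a, 1.0)
        self.r2 = pd.DataFrame(a, index=r2.index, columns=r2.columns)

    @property
    def snp_ids(self) -> list[str]:
        return self.r2.index.tolist()

    def get(self, a: str, b: str) -> float:
        """r2 for a SNP pair; unknown SNPs count as unlinked (0)."""
        if a == b:
            return 1.0
        if a in self.r2.index and b in self.r2.index:
            return float(self.r2.at[a, b])
        return 0.0

    def submatrix(self, snps: list[str]) -> np.ndarray:
        known = [s for s in snps if s in self.r2.index]
        out = np.zeros((len(snps), len(snps)))
        np.fill_diagonal(out, 1.0)
        if known:
            pos = {s: i for i, s in enumerate(snps)}
            sub = self.r2.loc[known, known].to_numpy()
            ii = [pos[s] for s in known]
            out[np.ix_(ii, ii)] = sub
        return out


def compute_ld(dosages: pd.DataFrame) -> LDMatrix:
    """LD r-squared as squared Pearson correlation of dosage columns.

    ``dosages`` is samples x SNPs (0..2). Constant columns have undefined
    correlation; their pairs are recorded as 0 with a warning.
    """
    if dosages.shape[0] < 2:
        raise FormatError("need >= 2 samples to compute LD")
    x = dosages.to_numpy(dtype=float)
    sd = x.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant SNP columns; their r2 recorded as 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r2 = np.nan_to_num(r, nan=0.0) ** 2
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(pd.DataFrame(r2, index=dosages.columns, columns=dosages.columns))


def read_dosages(path) -> pd.DataFrame:
    """Samples x SNPs dosage TSV (first column sample IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise FormatError("missing dosage values")
    return df


def read_ld_pairs(path, snp_ids: list[str] | None = None) -> LDMatrix:
    """Pairwise LD records: snp_a, snp_b, r2. Missing pairs are unlinked."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
    required = {"snp_a", "snp_b", "r2"}
    if not required.issubset(df.columns):
        raise FormatError(f"LD pair table missing columns: {sorted(required - set(df.columns))}")
    if ((df["r2"] < 0) | (df["r2"] > 1)).any():
        raise FormatError("r2 outside [0, 1]")
    ids = sorted(set(df["snp_a"]) | set(df["snp_b"]) | set(snp_ids or []))
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for a, b, r2 in df[["snp_a", "snp_b", "r2"]].itertuples(index=False):
        mat.at[a, b] = r2
        mat.at[b, a] = r2
    np.fill_diagonal(mat.values, 1.0)
    return LDMatrix(mat)


# ---------------------------------------------------------------------------
# Networks


@dataclass
class MolecularNetwork:
    """A molecular interaction graph (PPI or gene-regulatory) with provenance.

    Self-loops are dropped at load; undirected edges are stored once.
    """

    name: str
    graph: "object"  # nx.Graph | nx.DiGraph
    directed: bool = False

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def read_network(path, directed: bool = False, name: str | None = None) -> MolecularNetwork:
    """Two-column (or three-column; weight ignored) edge-list TSV with header."""
    import networkx as nx

    g = nx.DiGraph() if directed else nx.Graph()
    n_self = 0
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError("empty network file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise FormatError(f"unreadable edge at line {lineno}")
            a, b = _norm_symbol(fields[0]), _norm_symbol(fields[1])
            if a == b:
                n_self += 1
                g.add_node(a)
                continue
            g.add_edge(a, b)
    if n_self:
        logger.info("dropped %d self-loops loading %s", n_self, path)
    return MolecularNetwork(name=name or str(path), graph=g, directed=directed)


def write_network(net: MolecularNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for a, b in sorted(net.graph.edges()):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT) and annotations


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (GMT dialect)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno} has fewer than 3 fields")
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [_norm_symbol(m) for m in members if m.strip()]
            if not members:
                raise FormatError(f"GMT set {name!r} (line {lineno}) has no members")
            if name in sets:
                raise FormatError(f"duplicate GMT set name {name!r}")
            sets[name] = list(dict.fromkeys(members))
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_annotations(path) -> dict[str, list[str]]:
    """GO-style term annotation TSV: term_id <tab> gene (one pair per line)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"term_id", "gene_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation table missing columns: {sorted(required - set(df.columns))}")
    df["gene_id"] = df["gene_id"].map(_norm_symbol)
    out: dict[str, list[str]] = {}
    for term, grp in df.groupby("term_id", sort=True):
        genes = list(dict.fromkeys(grp["gene_id"]))
        if not genes:
            raise FormatError(f"term {term!r} has no genes")
        out[str(term)] = genes
    if not out:
        raise FormatError("annotation table is empty")
    return out


# ---------------------------------------------------------------------------
# Cross-species tables


def read_mouse_de(path) -> pd.DataFrame:
    """Mouse DE table: mouse_gene_id, q_value (optional direction column)."""
    df = pd.read_csv(path, sep="\t", dtype={"mouse_gene_id": str})
    required = {"mouse_gene_id", "q_value"}
    if not required.issubset(df.columns):
        raise FormatError(f"mouse DE table missing columns: {sorted(required - set(df.columns))}")
    df["mouse_gene_id"] = df["mouse_gene_id"].map(_norm_symbol)
    if df["mouse_gene_id"].duplicated().any():
        raise FormatError("duplicate mouse gene IDs")
    if ((df["q_value"] < 0) | (df["q_value"] > 1)).any():
        raise FormatError("q_value outside [0, 1]")
    return df


def read_orthologs(path) -> dict[str, str]:
    """Two-column mouse-to-human ortholog map (1:1)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"mouse_gene_id", "human_gene_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"ortholog map missing columns: {sorted(required - set(df.columns))}")
    m = df["mouse_gene_id"].map(_norm_symbol)
    h = df["human_gene_id"].map(_norm_symbol)
    if m.duplicated().any() or h.duplicated().any():
        raise FormatError("ortholog map is not 1:1")
    return dict(zip(m, h))
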