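"""Coexpression network: TOM oracle, module detection, eigengenes, overlaps."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from netdriver import coexpression as cx
from netdriver.io_formats import ExpressionMatrix, PhenotypeTable
from netdriver.synthetic_data import ModuleSpec, SimulationConfig, gen_expression


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap, straight from the formula."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    w = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            w[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return w


def _block_expression(rng, sizes, within=0.99, n_samples=80, noise_floor=0.05):
    rows, labels = [], []
    gi = 0
    for b, size in enumerate(sizes):
        f = rng.normal(size=n_samples)
        for _ in range(size):
            rows.append(np.sqrt(within) * f + np.sqrt(1 - within) * rng.normal(size=n_samples))
            labels.append(f"B{b}")
            gi += 1
    df = pd.DataFrame(rows, index=[f"G{i:03d}" for i in range(gi)],
                      columns=[f"S{i}" for i in range(n_samples)])
    return ExpressionMatrix(df), labels


class TestTOM:
    def test_matches_triple_loop_oracle(self, rng):
        for n in (10, 30, 50):
            r = rng.uniform(0, 1, size=(n, n))
            a = (r + r.T) / 2
            np.fill_diagonal(a, 1.0)
            assert np.allclose(cx.tom_from_adjacency(a), tom_oracle(a), atol=1e-10)

    def test_two_gene_clique_closed_form(self):
        a = np.array([[1.0, 1.0], [1.0, 1.0]])
        w = cx.tom_from_adjacency(a)
        assert w[0, 1] == pytest.approx(1.0)  # (0 + 1) / (1 + 1 - 1)

    def test_empty_adjacency_gives_empty_overlap(self):
        a = np.eye(5)
        w = cx.tom_from_adjacency(a)
        off = w[~np.eye(5, dtype=bool)]
        assert np.all(off == 0.0)


class TestSoftPower:
    def test_exact_power_law_fits_perfectly(self):
        # connectivity values placed at bin centers with power-law counts
        centers = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        counts = (centers ** -2.0 * 1000).astype(int)
        k = np.concatenate([np.full(c, v) for v, c in zip(centers, counts)])
        r2, slope = cx._scale_free_r2(k, n_bins=40)
        assert r2 > 0.97 and slope < 0

    def test_noise_genes_have_poor_fit_at_low_power(self, rng):
        expr = ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(60, 200)),
                         index=[f"G{i}" for i in range(60)],
                         columns=[f"S{i}" for i in range(200)])
        )
        fit = cx.pick_soft_power(expr, powers=range(1, 3), r2_threshold=0.8)
        assert not fit.passed  # warned fallback path

    def test_defaults_pass_on_synthetic_modules(self):
        cfg = SimulationConfig(seed=2)
        expr, phen, truth = gen_expression(cfg)
        from netdriver.preprocess import residualize

        resid = residualize(expr, phen, ["age", "sex", "bmi", "cells", "cohort"])
        fit = cx.pick_soft_power(resid)
        assert fit.passed and fit.power <= 20

    def test_zero_variance_gene_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 30)),
                          index=[f"G{i}" for i in range(40)],
                          columns=[f"S{i}" for i in range(30)])
        df.iloc[3] = 5.0
        with pytest.raises(ValueError, match="G3"):
            cx.build_network(ExpressionMatrix(df), 6)


class TestDetectModules:
    def test_separable_blocks_recovered_exactly(self, rng):
        expr, labels = _block_expression(rng, [40, 35, 30])
        net = cx.build_network(expr, 6)
        part = cx.detect_modules(net, min_size=30)
        pl = [part.labels[g] for g in net.gene_ids]
        assert cx.GREY not in pl
        assert adjusted_rand_score(labels, pl) == pytest.approx(1.0)

    def test_min_size_above_all_modules_gives_all_grey(self, rng):
        expr, labels = _block_expression(rng, [40, 35, 30])
        net = cx.build_network(expr, 6)
        part = cx.detect_modules(net, min_size=80)
        assert set(part.labels.values()) == {cx.GREY}

    def test_min_size_larger_than_gene_count_rejected(self, rng):
        expr, _ = _block_expression(rng, [40])
        net = cx.build_network(expr, 6)
        with pytest.raises(ValueError):
            cx.detect_modules(net, min_size=100)

    def test_invariant_under_gene_permutation(self, rng):
        expr, _ = _block_expression(rng, [40, 35, 30])
        perm = rng.permutation(expr.n_genes)
        shuffled = ExpressionMatrix(expr.data.iloc[perm])
        p1 = cx.detect_modules(cx.build_network(expr, 6))
        p2 = cx.detect_modules(cx.build_network(shuffled, 6))
        genes = expr.gene_ids
        l1 = [p1.labels[g] for g in genes]
        l2 = [p2.labels[g] for g in genes]
        assert adjusted_rand_score(l1, l2) == pytest.approx(1.0)


class TestEigengenes:
    def test_identical_genes_give_rank_one_module(self, rng):
        profile = rng.normal(size=50)
        df = pd.DataFrame([profile] * 10, index=[f"G{i}" for i in range(10)],
                          columns=[f"S{i}" for i in range(50)])
        # tiny jitter keeps per-gene variance nonzero but preserves rank-1 structure
        df += rng.normal(scale=1e-6, size=df.shape)
        expr = ExpressionMatrix(df)
        part = cx.ModulePartition(labels={g: "turquoise" for g in expr.gene_ids})
        eig, var_exp = cx.eigengenes(expr, part)
        assert var_exp["turquoise"] > 0.999
        z = (profile - profile.mean()) / profile.std()
        cos = abs(np.dot(eig.loc["turquoise"], z / np.linalg.norm(z)))
        assert cos > 1 - 1e-6

    def test_matches_eigendecomposition_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 60)),
                          index=[f"G{i}" for i in range(20)],
                          columns=[f"S{i}" for i in range(60)])
        expr = ExpressionMatrix(df)
        part = cx.ModulePartition(labels={g: "blue" for g in expr.gene_ids})
        eig, var_exp = cx.eigengenes(expr, part)
        z = (df.to_numpy() - df.to_numpy().mean(1, keepdims=True))
        z = z / z.std(1, keepdims=True)
        evals, evecs = np.linalg.eigh(z.T @ z)  # samples x samples
        top = evecs[:, -1]
        cos = abs(np.dot(eig.loc["blue"], top))
        assert cos >= 1 - 1e-8
        assert var_exp["blue"] == pytest.approx(evals[-1] / evals.sum())

    def test_sign_orientation_restores_flipped_members(self, rng):
        df = pd.DataFrame(rng.normal(size=(8, 40)) + rng.normal(size=40),
                          index=[f"G{i}" for i in range(8)],
                          columns=[f"S{i}" for i in range(40)])
        expr = ExpressionMatrix(df)
        part = cx.ModulePartition(labels={g: "red" for g in expr.gene_ids})
        eig1, _ = cx.eigengenes(expr, part)
        flipped = ExpressionMatrix(-df)
        eig2, _ = cx.eigengenes(flipped, cx.ModulePartition(labels=dict(part.labels)))
        # orientation rule makes the summary reproducible up to overall sign flip
        # of the data: correlation magnitude with members is unchanged
        assert abs(np.dot(eig1.loc["red"], eig2.loc["red"])) == pytest.approx(1.0)


class TestModuleTrait:
    def _phen(self, eig_row, n):
        df = pd.DataFrame(
            {
                "sbp": eig_row * 14 + 118,
                "dbp": np.random.default_rng(0).normal(74, 9, n),
                "age": 50.0, "sex": 0, "bmi": 27.0, "cohort": "a",
            },
            index=[f"S{i}" for i in range(n)],
        )
        df["age"] = np.random.default_rng(1).normal(50, 10, n)
        return PhenotypeTable(df)

    def test_eigengene_equal_to_trait(self, rng):
        n = 60
        eig = pd.DataFrame([rng.normal(size=n)], index=["turquoise"],
                           columns=[f"S{i}" for i in range(n)])
        phen = self._phen(eig.loc["turquoise"].to_numpy(), n)
        out = cx.module_trait(eig, phen)
        row = out[(out["module"] == "turquoise") & (out["trait"] == "sbp")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-50

    def test_fdr_dominates_p(self, rng):
        n = 50
        eig = pd.DataFrame(rng.normal(size=(5, n)),
                           index=["m1", "m2", "m3", "m4", "m5"],
                           columns=[f"S{i}" for i in range(n)])
        phen = self._phen(rng.normal(size=n), n)
        out = cx.module_trait(eig, phen)
        assert (out["fdr"] >= out["p"] - 1e-15).all()
        assert (out["min_p_module"] == out.groupby("module")["p"].transform("min")).all()


class TestModuleSignature:
    def test_signature_inside_one_module(self, rng):
        labels = {f"G{i}": "turquoise" if i < 30 else ("blue" if i < 60 else cx.GREY)
                  for i in range(300)}
        part = cx.ModulePartition(labels=labels)
        signature = [f"G{i}" for i in range(15)]  # all inside turquoise
        res = {r.name: r for r in cx.module_signature_enrichment(part, signature)}
        assert res["turquoise"].p < 1e-8
        assert res["blue"].p > 0.5

    def test_counts_match_hand_enumerated_toy(self):
        # 20 genes, module of 6, signature of 5, overlap 3
        labels = {f"G{i}": "turquoise" if i < 6 else cx.GREY for i in range(20)}
        part = cx.ModulePartition(labels=labels)
        signature = ["G0", "G1", "G2", "G10", "G11"]
        res = cx.module_signature_enrichment(part, signature)[0]
        assert (res.k, res.n, res.K, res.N) == (3, 6, 5, 20)
        # exhaustive hypergeometric tail
        expect = sum(
            math.comb(5, k) * math.comb(15, 6 - k) for k in range(3, 6)
        ) / math.comb(20, 6)
        assert res.p == pytest.approx(expect, rel=1e-12)


class TestModuleOverlap:
    def _part(self, assignment):
        return cx.ModulePartition(labels=dict(assignment))

    def test_identity_partitions_fully_conserved(self):
        labels = {f"G{i}": ["turquoise", "blue", "brown"][i % 3] for i in range(150)}
        part = self._part(labels)
        out = cx.module_overlap(part, part)
        conserved_pairs = dict(out["conserved"])
        assert all(conserved_pairs[m] == m for m in part.modules)

    def test_split_module_detected(self):
        a = {f"G{i}": "turquoise" if i < 80 else "blue" for i in range(160)}
        b = {}
        for i in range(160):
            if i < 40:
                b[f"G{i}"] = "green"
            elif i < 80:
                b[f"G{i}"] = "red"
            else:
                b[f"G{i}"] = "yellow"
        out = cx.module_overlap(self._part(a), self._part(b))
        assert set(out["splits"].get("turquoise", [])) == {"green", "red"}

    def test_random_partitions_not_conserved(self, rng):
        mods = ["turquoise", "blue", "brown", "yellow"]
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            a = {f"G{i}": mods[r.integers(4)] for i in range(200)}
            b = {f"G{i}": mods[r.integers(4)] for i in range(200)}
            out = cx.module_overlap(self._part(a), self._part(b))
            hits += bool(out["conserved"])
        assert hits <= 1  # conserved pairs essentially never arise by chance
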