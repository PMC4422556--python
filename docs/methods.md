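# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer would want recorded.

## Covariate adjustment

Expression is adjusted per gene by ordinary least squares on an intercept
plus the requested covariates (age in years, sex 0/1, BMI in kg/m²,
blood cell-type proportions in [0,1], cohort as indicator columns).
Categorical covariates expand to drop-first dummies; collinear columns are
dropped greedily before fitting (the cell proportions sum to one, so one
of them is always absorbed). Residuals are exactly orthogonal to the
retained design and residualization is idempotent.

The classical analysis in this setting uses linear *mixed* models with a
kinship random effect. This package substitutes fixed-effects OLS: it has
no pedigree machinery, and the synthetic cohort is unrelated individuals,
for which the two coincide. With related samples the fixed-effects
p-values would be anticonservative; that analysis is out of scope.

A dual analysis track (with and without cell-type adjustment) is a single
config flag (`adjust_cell_types`), rerunning the identical pipeline, and
`module_overlap` quantifies module correspondence between the two tracks
(Fisher overlap per module pair, Bonferroni over pairs, conservation =
significant reciprocal best match).

## Single-gene associations

Each trait is tested against each gene's residual expression with a
Pearson correlation t-test (two-sided), equivalent to the slope test of
`trait ~ expression`. Hypertension (SBP ≥ 140 mm Hg or DBP ≥ 90 mm Hg) is
kept in the same linear score test rather than logistic regression so all
three traits share one framework; with a 0/1 outcome this is the score
test of association and is well calibrated under the null. The signature
set is the union of genes passing `p < α / n_genes` for any trait
(α = 0.05), with per-trait counts and sign tallies reported.

## Coexpression network

* **Unsigned adjacency** `|r|^β`: the correlation sign is discarded, the
  default convention of the underlying WGCNA methodology.
* **Soft power selection**: for β = 1..20, connectivity `k_i = Σ a_ij` is
  binned into 10 equal-width bins; `log10` relative frequency is regressed
  on `log10` bin center over occupied bins. The fit index is R² signed by
  the slope (a rising p(k) can never qualify as scale-free); the smallest
  β with index > 0.8 wins, else the argmax with a warning.
* **TOM** with the min-connectivity denominator, computed by matrix
  product; a brute-force triple loop is kept in the tests as the oracle
  (agreement to 1e-10 on all fixtures ≤ 50 genes).
* **Branch cut**: average-linkage clustering on `1 − TOM`. Soft
  thresholding acts multiplicatively, so at the higher selected powers all
  dissimilarities compress toward 1 and a cut at a fixed fraction of the
  maximum merge height lands *inside* real branches. The cut is therefore
  placed at the largest gap of `−log10(1 − h)` among the upper half of the
  merge heights — a multiplicative scale on which module-internal and
  module-separating merges stay separated at any power — falling back to
  `0.99 × max(h)` when no gap dominates (unstructured data). Branches of
  ≥ `min_size` (default 30) genes become modules, recursively re-split at
  their root merges while both halves remain ≥ `min_size`; the remainder
  is grey. This replaced the fixed-height rule after module recovery on
  the default conditions went from ARI ≈ 0.1 (powers 10–18) to 1.0.
* **Eigengenes**: first right singular vector of the gene-standardized
  member block, unit norm, sign oriented so the mean correlation with
  members is ≥ 0; `variance_explained = s₁²/Σs²`.
* No module-eigengene merging by default (flag available in the library by
  re-running detection on merged labels); module colors are a fixed
  40-name vocabulary assigned by size rank and carry no meaning.

Module–trait association correlates eigengenes with the *raw* trait
values (the traits are not residualized), with BH-FDR across module ×
trait pairs and tier flags at p < 0.05, FDR < 0.2, FDR < 0.05. Because the
raw traits contain covariate variance that the eigengenes are orthogonal
to, the test is slightly conservative in absolute terms; the pure-null
calibration in the tests therefore switches the generator's trait
covariate effects off.

## SNP-set enrichment

* **Pruning** is greedy clumping at r² ≥ 0.8. The kept SNP is the one with
  the best *eQTL* p (ties broken lexicographically by SNP id): selection
  must not peek at the GWAS outcome under test or the null is biased.
  The output is canonical (independent of input order). Missing LD pairs
  count as unlinked.
* **Background** = all eSNPs after the same pruning. The tested set's SNPs
  are *not* removed from the background; the comparison is "set vs all",
  which is slightly conservative for large sets.
* **Tests**: one-sided two-sample KS (alternative: set p-values
  stochastically smaller) and one-sided Fisher on the 2×2 of
  (set/background) × (GWAS p < 0.05 or not), applied to the same pruned
  SNP lists so the two statistics are comparable.
* **Permutations** draw equal-sized gene sets from the pool of genes with
  ≥ 1 eSNP and rerun the full chain; the empirical p counts strict
  improvements only (`perm p < observed p`), reported as "<1/n_perm" when
  nothing beats the observed value.
* **Causal call**: both analytic tests Bonferroni-significant (corrected
  over the number of sets tested) for at least one trait.

## Key-driver analysis

Candidates are every node of the gene set's 3rd-layer expanding network
(union of ≤3-step neighborhoods of the set members present in the
network, plus the members). For each candidate, a one-sided
Fisher/hypergeometric test of its ≤3-step neighborhood against the set,
over all network nodes minus the candidate; Bonferroni count = candidate
pool size (an `all_nodes` alternative is a flag). Directed networks are
expanded ignoring edge direction by default (downstream-only behind a
flag). The candidate is excluded from its own neighborhood and universe;
set members may themselves be KDs.

Raw significant calls necessarily come in clumps: any node within twice
the search depth of an enriched hub shares part of the hub's neighborhood
and inherits its signal. `filter_local_peaks` therefore walks significant
candidates in ascending p order and keeps one per region (suppressing
candidates whose neighborhoods overlap a stronger kept candidate, i.e.
within graph distance 2 × depth). The pipeline reports the filtered list;
`kd_scan` itself returns every candidate. Replication in a second network
means Bonferroni significance there for the same gene set, over testable
(present) KDs. Ranking tiers: GWAS (own eSNP with GWAS p < 1e-5, sorted by
that p), then TWAS (transcriptome-wide Bonferroni-significant trait
association), then multi-network, then the rest by kd_p.

## Subnetworks and enrichment

Genetic subnetworks are SNP-centered stars with cis/trans edge labels;
interaction subnetworks are induced subgraphs on a KD plus its ≤3-step
neighborhood. All overlap tests share one statistic: hypergeometric upper
tail P(X ≥ k) with `fold = (k/n)/(K/N)`; the universe is always an
explicit argument and is never inferred from the inputs, because silent
universe defaults are the classic way these tests go wrong. Mouse DE genes
are called at q < 0.05 and mapped through a 1:1 ortholog table; direction
of change is ignored. GO-style annotation enrichment corrects by the
number of terms in the table (0.05/825 ≈ 6e-5 for a full
biological-process table).

## Synthetic data

The generator emulates, with planted ground truth: coexpressed modules
(Gaussian single-factor blocks, `x = √ρ·f + covariate terms + √(1−ρ)·ε`),
traits linear in the module factors and covariates and scaled to mm Hg
(SBP 118 ± 14, DBP 74 ± 9, hypertension by thresholding — about 10%
prevalence), block-LD genotypes (copy-with-flip-noise, within-block
r² ≳ 0.8), an eSNP map with one LD block per gene, GWAS p-values from a
noncentral χ²(1) tail for causal-module eSNPs and Uniform(0,1) otherwise,
a preferential-attachment interaction network with planted hub drivers,
and a knockout DE list concentrated in a chosen hub's neighborhood.

Defaults (the study conditions of the test suite): 200 samples, 500 genes,
six 50-gene modules at within-correlation 0.6, trait loadings |r| ≈ 0.1
(the weak-signal regime of population transcriptomics; individual genes
rarely reach transcriptome-wide significance at this n, modules do),
four causal modules at GWAS noncentrality 30 (median causal eSNP
p ≈ 5e-8), 1,500 SNPs in blocks of 3, two planted hubs of degree ~41
tethered to the periphery of a 1,500-node attachment graph with
neighborhood enrichment 0.7, mouse perturbation 0.4 vs background 0.15.
Planted hubs are built as attached stars (rather than relabeled core
nodes) because in a small attachment graph the core's 3-step balls cover
half the network, which destroys both the contrast and the disjointness a
recovery benchmark needs; hub neighborhoods are filled closest-first so
the enrichment concentrates on the hub itself. Null-calibration
experiments scale the gene pool up (2,000 genes, 6,000 SNPs) so that
1,000 random sets are nearly disjoint and their test statistics nearly
independent.

A single seed is expanded into per-stage substreams via counter-keyed
`SeedSequence`s; identical seed + config gives byte-identical output
files.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: family structure and kinship confounding,
count-based expression noise (Gaussian factors only), realistic LD decay
and allele-frequency spectra, many-to-many orthology, hub genes shared
between modules, and assortative or modular topology in the interaction
network beyond preferential attachment.

## Numerical choices and degenerate inputs

Zero-variance genes are an error in network construction and eigengene
computation, p = 1 with a warning in the cell-type scan. Constant traits
are an error. Constant dosage columns get r² = 0 with a warning.
Correlations are clipped to [−1, 1] before t-transforms; p-values are
floored at the smallest positive double. Empty gene-set/eSNP
intersections propagate as an explicit `no_esnps` status, not an
exception. All tabular outputs are TSV; run summaries are JSON.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at the
default conditions above: 10 seeds for recovery benchmarks, 20 seeds for
family-wise null checks, 1,000 random sets for the SSEA uniformity check,
100–1,000 permutations where permutation p-values are exercised. These
sizes are the package's own trade-off between statistical resolution and
a test suite that runs in minutes on a laptop.

## Known limitations

Fixed-effects covariate adjustment (no kinship); no Bayesian-network
structure learning (directed networks are consumed as inputs); no
block-wise TOM for very large gene counts (dense matrices throughout,
comfortable to ~5,000 genes); the dynamic branch cut is a simplified
gap-based variant, not a port of the published hybrid algorithm — module
*recovery*, not algorithmic identity, is its contract; single-factor
modules mean the generator cannot produce nested or overlapping module
structure.
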