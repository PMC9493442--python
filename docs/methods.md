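# Methods

This document describes the statistical methods implemented in
`macroindex`, the synthetic-cohort model used to validate them, the main
parameters and their defaults, and the known limitations.

## 1. Input model

All analyses operate on four tables keyed by sample id:

- **Expression**: genes × samples, non-negative TPM values. Duplicate gene
  rows are collapsed by mean (with a warning); duplicate sample columns are
  rejected.
- **Fractions**: one cell-type × sample matrix per estimation algorithm,
  columns summing to 1, optionally with per-sample estimation p-values.
- **Clinical**: per-sample phenotypes; `os_time`/`os_event` and
  `pfi_time`/`pfi_event` are validated (non-negative times, binary events)
  when present.
- **Alterations**: binary feature × sample matrix.

`harmonize` intersects sample ids across tables (requiring ≥ 3 shared
samples), reorders everything to the expression order, and reports what
was dropped. Gene sets use GMT files.

## 2. Immune consensus clustering

Samples with fraction-estimation p > 0.05 are removed, as are cell types
that are zero in strictly more than half of the remaining samples.

Clustering is PAM (k-medoids; greedy build followed by swap steps) on the
distance 1 − Pearson correlation between sample fraction profiles. For
each k in 2..6, the data are subsampled 1000 times at 80% of samples; the
consensus matrix entry M(i, j) is the number of times i and j co-cluster
divided by the number of times both were sampled. The **PAC** (proportion
of ambiguous clustering) is the fraction of off-diagonal consensus entries
strictly between 0.1 and 0.9; k is chosen to minimize PAC (ties go to the
smallest k). Cluster stability is summarized by silhouette widths computed
on the consensus dissimilarity 1 − M, and the top 75% of samples per
cluster by silhouette (ceiling, ties broken by sample id) are flagged as
**core** samples.

With k = 2, the cluster with the higher mean M2 fraction is the M2-rich
cluster; core samples are labelled Macro1 (GBM ∩ M2-rich), Macro2
(LGG ∩ M2-rich) and Macro3 (LGG ∩ M2-poor); GBM samples in the M2-poor
cluster stay unlabelled.

Defaults: `k_min=2, k_max=6, n_resample=1000, subsample_frac=0.8`,
PAC bounds (0.1, 0.9), `keep_frac=0.75`. The resampling depth follows
common consensus-clustering practice; PAC bounds are the standard
"ambiguity" window.

## 3. Enrichment

**ssGSEA.** Per sample, genes receive average ranks of their expression.
Walking the genes in decreasing rank order, the score accumulates the
difference between the weighted in-set ECDF (weights |rank|^0.25) and the
unweighted out-of-set ECDF at every position. Scores are min–max
normalized over the whole score matrix. Sets with fewer than two genes
present are skipped with a warning. The exponent 0.25 is the classical
ssGSEA weighting.

**Preranked GSEA.** Given a ranked list (Spearman correlation against a
target vector, or log2 fold change between groups), the enrichment score
is the maximum deviation of a running sum with hit increments
∝ |metric|^p (p = 1 by default) and constant miss decrements 1/(N − |S|).
Significance comes from gene-label permutations preserving set size: exact
enumeration when C(N, |S|) ≤ 100 000, otherwise random permutations with
the (r + 1)/(n + 1) estimator. NES divides the ES by the mean |permuted
ES| of the same sign; FDR uses the pooled-NES ratio. Set-size window
5–500.

## 4. M2 association

**Regression consensus.** For each fraction-estimation algorithm, the M2
fraction is regressed (OLS) on the candidate features after backward VIF
elimination (drop the highest-VIF feature until all VIF < 5; the stated
VIF criterion is applied directly rather than an AIC stepwise search). A
feature's consensus verdict is **positive** iff at least two algorithms
give p < 0.05 with β > 0 and no algorithm gives a significant β < 0
(mirrored for negative), else **none**.

**Alterations.** Each binary alteration is the response of a logistic
regression on the standardized M2 fraction (Wald p). Quasi-separation and
near-empty classes are flagged not-estimable rather than reported with
spurious confidence.

**Fisher exact r×c (Freeman–Halton).** For categorical clinical
contrasts. All tables with the observed margins are enumerated
recursively; p is the total probability of tables whose hypergeometric
probability is ≤ the observed one (relative slack 1e-7). Above 10^7
tables the test switches to Monte-Carlo sampling of margin-fixed tables
(Patefield algorithm, 10^6 draws by default, standard error reported).
Verified against R's `fisher.test` and, on 2×2 tables, against
`scipy.stats.fisher_exact`.

## 5. The Macro index

Mean log2(TPM + 1) of PIK3R5, PIK3R6, ALOX5, ALOX5AP and ALOX15B. At
least four of the five genes must be present (`min_present=4`); otherwise
the computation errors rather than silently rescaling. Samples are split
at the median (strictly greater → "high"). Differential expression
between the groups uses the Wilcoxon rank-sum test (exact enumeration for
small groups) with Benjamini–Hochberg correction; hit signatures take the
top/bottom 150 genes by log2 fold change (ties broken by gene id).

## 6. Signature concordance (rho-ROC)

Each hit gene's Spearman correlation with the Macro index is a classifier
score; positive hits are the positive class. Genes with correlation
p ≥ 0.05 are excluded by default. The ROC is summarized by the
Mann–Whitney AUC (ties count one half), which makes the AUC invariant to
strictly increasing transforms of the index.

## 7. Survival

Kaplan–Meier with Greenwood confidence intervals, the two-group log-rank
test, and univariate Cox proportional hazards with Efron tie handling
(all via lifelines). Cox requires ≥ 10 events; non-convergence is
returned flagged, not raised. Relapse groups from the progression-free
interval: GBM early = PFI < 6 months with an observed event, late =
PFI > 12 months (censoring admitted); LGG uses a 5-year cutoff on both
sides. Months are 30.44 days, years 365.25 days.

## 8. Synthetic cohort model

The generator produces a fully ground-truthed cohort:

- **Fractions**: six cell types; each sample draws its immune fraction
  vector from one of two Dirichlet archetypes — M2-high α = (8,2,2,2,2,2)
  (M2 first) or M2-low α = (1,4,4,4,4,4). Half the samples per archetype;
  the M2-high half is labelled GBM, the rest LGG.
- **Bulk expression**: a quarter of genes are cell-type markers forming a
  signature matrix S; bulk = S·F rescaled to 10^6 per column, with
  log-normal noise (σ = 0.25 on the log2 scale).
- **Index genes**: log2(TPM+1) = a + 4·f_M2 + N(0, 0.5) for the five
  Macro-index genes — a noisy linear readout of the true M2 fraction.
- **Hit genes**: 150 up / 150 down genes shifted by ±2.0·z(f_M2) log2
  units. The shift is large because these genes emulate the *top-ranked*
  DEGs of a stimulation experiment: they must out-rank incidental marker
  differences, exactly as top DEGs do by construction.
- **Fraction replicates**: three "algorithms" = truth + independent
  noise, with estimation p-values ~ U(0, 0.04).
- **Survival**: exponential OS/PFI times with log-hazard 0.8 per standard
  deviation of the true index signal, plus independent censoring.
- **Alterations**: binary features whose log-odds follow the standardized
  M2 fraction with slope 2.0, plus null features.

What the generator does **not** emulate: compositional dependence between
cell types beyond the Dirichlet draw, batch effects, isoform-level
structure, copy-number-driven expression, or realistic gene-gene
correlation beyond the mixture. Results on it validate the *machinery*,
not biological effect sizes.

## 9. Validation experiments and numerical choices

- NNLS deconvolution recovery is evaluated on the marker genes only: the
  planted index/hit genes intentionally violate the linear mixture model.
  Per-cell-type RMSE is ≈ 0.01–0.02 at expression noise 0.2.
- Macro-group agreement with ground truth is asserted at ≥ 0.95 on core
  samples: the two Dirichlet archetypes overlap in fraction space, so a
  small fraction of samples is genuinely ambiguous even under perfect
  clustering of the observed fractions.
- The sign-consensus type-I experiment draws three *independent*
  algorithm estimates: the < 1% guarantee is a property of the 2-of-3
  decision rule under independent evidence. When the algorithms' errors
  are nearly perfectly correlated (e.g. replicates of the same estimate),
  consensus degenerates to a single 5% test — a real limitation of
  consensus rules that users should keep in mind when their fraction
  algorithms share a method family. The planted-effect experiment keeps a
  shared latent truth with independent per-algorithm noise and mutually
  orthogonal planted components (so VIF reduction keeps all of them);
  measured FDR ≈ 0.04–0.07, recovery ≈ 0.8.
- Cox recovery is validated on exponential survival with log-HR ln 2:
  mean estimate within ±0.15 and CI coverage ≈ 94–96% over 500 runs.
- Exact enumerations (Fisher r×c, Wilcoxon, GSEA permutations) switch to
  sampling approximations above explicit size bounds (10^7 tables,
  group size 25, 10^5 combinations) — chosen so the exact paths stay
  under a second on one CPU.
- Default problem sizes (160 samples, 1200 genes) are package choices for
  fast, fully-powered validation; every size is configurable through
  `SimulationConfig` and `RunConfig`.

## 10. Limitations

- The Macro index is a bulk-mRNA surrogate; it cannot distinguish more
  M2 cells from higher per-cell expression.
- The Freeman–Halton test is exact but exponential in table size; large
  sparse tables fall back to Monte-Carlo with a reported standard error.
- PAM consensus clustering is O(n² · resamples); very large cohorts need
  a lower `n_resample`.
- The relapse-group rule discards censored-early and mid-interval
  samples, which can bias comparisons when censoring is informative.
- ssGSEA scores are min–max normalized over the analyzed matrix, so they
  are comparable within a run, not across cohorts.
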