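# macroindex

Immune-cluster stratification of glioma expression cohorts and the
five-gene **Macro index**, a transcriptional surrogate of M2 (alternatively
activated) macrophage content.

Gliomas differ sharply in how much of their bulk is tumour-associated
macrophage rather than tumour cell, and the M2-polarized fraction in
particular tracks grade and outcome. This package implements an end-to-end
analysis of that axis on bulk RNA-seq cohorts:

1. **Immune clustering** — consensus clustering (PAM k-medoids over
   1 − Pearson distance with subsampling) of per-sample immune-cell
   fraction estimates; the number of clusters is chosen by the proportion
   of ambiguous clustering (PAC), cluster stability is summarized by
   silhouette widths on the consensus matrix, and the best-separated 75%
   of each cluster is kept as "core" samples. With two clusters, core
   samples are labelled **Macro1** (GBM, M2-rich cluster), **Macro2**
   (LGG, M2-rich cluster) and **Macro3** (LGG, M2-poor cluster).
2. **Enrichment** — single-sample GSEA (weighted ECDF difference,
   exponent 0.25, global min–max normalization) and preranked GSEA with
   gene-label permutations (exact enumeration when feasible).
3. **Association** — which pathway scores track the M2 fraction, by
   multiple linear regression against each fraction-estimation algorithm
   after VIF-driven collinearity reduction (VIF < 5), combined by a
   sign-consensus rule (≥ 2 algorithms significant with agreeing sign,
   none significant with the opposite sign). Genomic alterations are
   related to M2 content by logistic regression. Categorical clinical
   contrasts use a hand-written Freeman–Halton Fisher exact test for
   r×c tables (verified against R's `fisher.test`).
4. **Macro index** — mean log2(TPM + 1) of PIK3R5, PIK3R6, ALOX5,
   ALOX5AP and ALOX15B (leukotriene-synthesis genes expressed chiefly by
   monocytes/macrophages); median split, rank-sum differential
   expression, and ±150-gene hit signatures.
5. **Concordance** — a rho-ROC: per hit gene, Spearman correlation with
   the Macro index is used as a classifier score for positive vs
   negative hits, summarized by the Mann–Whitney AUC.
6. **Survival** — Kaplan–Meier, log-rank, univariate Cox (Efron ties),
   and early/late relapse grouping from the progression-free interval.
7. **Synthetic cohort** — a fully ground-truthed generator (Dirichlet
   immune fractions with M2-high/M2-low archetypes, signature-driven bulk
   expression, planted index/hit genes, exponential survival tied to the
   index, planted alteration–M2 couplings) on which every stage of the
   pipeline is exercised and validated.

## Worked example

```python
from macroindex import (
    SimulationConfig, simulate_cohort, ConsensusClusterer,
    filter_fraction_matrix, compute_macro_index, split_by_median,
    signature_concordance_auc, logrank_test, cox_univariate, spearman,
    M2_CELL_TYPE,
)

cohort = simulate_cohort(SimulationConfig(seed=1))          # 160 samples, 1200 genes

# 1. consensus clustering of the immune fractions
fr = cohort.fraction_set
filtered = filter_fraction_matrix(fr.fractions["algoA"], fr.pvalues["algoA"])
model = ConsensusClusterer(random_state=1).fit(filtered.T)
model.chosen_k_          # 2   (PAC at k=2 is 0.037; >= 0.185 for k=3..6)

# 2. the Macro index tracks the true M2 fraction
mi = compute_macro_index(cohort.expression)
rho, p = spearman(mi.values, cohort.truth.fractions.loc[M2_CELL_TYPE])
rho                      # 0.939

# 3. hit-signature concordance
res = signature_concordance_auc(cohort.expression, mi,
                                cohort.truth.hit_up, cohort.truth.hit_dn)
res.auc                  # 1.0 over 300 significant hit genes

# 4. survival: index-high does worse
clin = cohort.clinical.data
groups = split_by_median(mi.values)
chi2, p = logrank_test(clin["os_time"], clin["os_event"], groups)
p                        # 1.9e-19
cox = cox_univariate(clin["os_time"], clin["os_event"], mi.values)
cox.hr                   # 3.22 per unit of index
```

The same analysis runs from the command line:

```bash
macroindex run --config run.yaml      # full pipeline from one YAML config
macroindex simulate --out cohort/ --seed 1
macroindex cluster --fractions cohort/fractions_algoA.tsv --out clu/
macroindex index --expr cohort/expression.tsv --out index.tsv
macroindex table1                     # Fisher exact p-values, published tables
```

Exit codes: 0 ok, 2 configuration error, 3 data error, 4 numerical failure.

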