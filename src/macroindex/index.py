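"""The Macro index and downstream expression summaries.

The Macro index is the mean log2-transformed TPM (with +1 pseudocount) of
five leukotriene-synthesis genes expressed chiefly by monocytes and
macrophages: PIK3R5, PIK3R6, ALOX5, ALOX5AP and ALOX15B. It serves as an
mRNA surrogate of the alternatively activated (M2) macrophage content of
a glioma sample and is the covariate every downstream comparison keys on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .association import wilcoxon_rank_sum
from .io import ExpressionMatrix

__all__ = [
    "MACRO_INDEX_GENES",
    "MacroIndexVector",
    "compute_macro_index",
    "split_by_median",
    "differential_expression",
    "hit_signatures",
    "aggregate_signature_score",
]

MACRO_INDEX_GENES = ("PIK3R5", "PIK3R6", "ALOX5", "ALOX5AP", "ALOX15B")


@dataclass
class MacroIndexVector:
    values: pd.Series  # sample -> index
    gene_list: list[str]
    n_genes_found: int


def compute_macro_index(
    expr: ExpressionMatrix,
    genes=MACRO_INDEX_GENES,
    min_present: int = 4,
) -> MacroIndexVector:
    """Mean log2(TPM + 1) of the index genes per sample.

    Errors when fewer than ``min_present`` of the genes are found rather
    than silently rescaling over a different gene list.
    """
    found = [g for g in genes if g in expr.values.index]
    missing = [g for g in genes if g not in expr.values.index]
    if len(found) < min_present:
        raise ValueError(
            f"only {len(found)}/{len(genes)} index genes present; missing {missing}"
        )
    block = np.log2(expr.values.loc[found].to_numpy() + 1.0)
    vals = pd.Series(block.mean(axis=0), index=expr.values.columns, name="macro_index")
    return MacroIndexVector(vals, found, len(found))


def split_by_median(values: pd.Series) -> pd.Series:
    """Label samples "high" (> median) or "low" (<= median)."""
    values = pd.Series(values)
    med = values.median()
    labels = pd.Series(np.where(values > med, "high", "low"), index=values.index)
    if (labels == "low").all():
        warnings.warn("degenerate split: no sample exceeds the median")
    return labels


def differential_expression(
    expr: ExpressionMatrix, groups: pd.Series, exact_below_n: int = 25
) -> pd.DataFrame:
    """Rank-sum differential expression, high vs low group.

    Per gene: log2 fold change as the difference of mean log2(TPM+1)
    between groups, Wilcoxon rank-sum p, and Benjamini-Hochberg q.
    """
    groups = pd.Series(groups).loc[expr.values.columns]
    hi = groups[groups == "high"].index
    lo = groups[groups == "low"].index
    if len(hi) < 3 or len(lo) < 3:
        raise ValueError("need >= 3 samples per group")
    log_expr = np.log2(expr.values + 1.0)
    lfc = log_expr[hi].mean(axis=1) - log_expr[lo].mean(axis=1)
    pvals = np.array([
        wilcoxon_rank_sum(
            expr.values.loc[g, hi].to_numpy(),
            expr.values.loc[g, lo].to_numpy(),
            exact_below_n=exact_below_n,
        )[0]
        for g in expr.values.index
    ])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": lfc, "p": pvals, "q": qvals}, index=expr.values.index
    )


def hit_signatures(de: pd.DataFrame, n: int = 150) -> tuple[list[str], list[str]]:
    """Top/bottom ``n`` genes by log2 fold change (ties broken by gene id)."""
    if 2 * n > len(de):
        raise ValueError(f"need at least {2 * n} genes for n = {n} per direction")
    by_id = de.loc[sorted(de.index)]
    positive = list(by_id.sort_values("log2fc", ascending=False, kind="mergesort").index[:n])
    negative = list(by_id.sort_values("log2fc", ascending=True, kind="mergesort").index[:n])
    return positive, negative


def aggregate_signature_score(expr: ExpressionMatrix, gene_set) -> pd.Series:
    """Mean per-gene z-score of log2(TPM+1) over a gene set, per sample.

    Zero-variance genes are dropped with a warning; genes absent from the
    matrix are ignored.
    """
    present = [g for g in gene_set if g in expr.values.index]
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    block = np.log2(expr.values.loc[present].to_numpy() + 1.0)
    sd = block.std(axis=1, ddof=0)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"{int((~keep).sum())} zero-variance gene(s) dropped")
        block, sd = block[keep], sd[keep]
        if block.size == 0:
            raise ValueError("all signature genes have zero variance")
    z = (block - block.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.Series(z.mean(axis=0), index=expr.values.columns, name="signature_score")
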