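"""Signature-concordance ROC: how well the Macro index separates the
positive from the negative hit genes of a macrophage-condition signature.

Each hit gene's Spearman correlation with the Macro index across samples
is used as a classifier score; positive hits are the positive class. The
ROC is taken over thresholds on rho and summarized by the Mann-Whitney
AUC (ties counted one half), so the AUC is invariant to any strictly
increasing transform of the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .association import spearman
from .index import MacroIndexVector
from .io import ExpressionMatrix

__all__ = ["ConcordanceResult", "signature_concordance_auc", "roc_curve"]


@dataclass
class ConcordanceResult:
    per_gene: pd.DataFrame  # rho, p, label, included
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_included: int
    n_dropped_absent: int


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC points ordered by threshold plus the Mann-Whitney AUC.

    On tie-free scores the trapezoidal area under the returned points
    equals the U-statistic value; with ties the AUC reported here is the
    tie-corrected U/(n1*n2).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return fpr, tpr, thr, auc


def signature_concordance_auc(
    expr: ExpressionMatrix,
    index: MacroIndexVector | pd.Series,
    positive_hits,
    negative_hits,
    sig_alpha: float = 0.05,
    filter_significant: bool = True,
    samples=None,
) -> ConcordanceResult:
    """Concordance of the Macro index with a positive/negative hit-gene pair.

    Computes rho(gene, index) per hit gene present in the matrix, keeps
    genes with p below ``sig_alpha`` (unless ``filter_significant`` is
    off), labels positives 1 / negatives 0 and returns the ROC over rho.
    ``samples`` optionally restricts the correlation to a sample subset
    (e.g. one Macro group).
    """
    idx = index.values if isinstance(index, MacroIndexVector) else pd.Series(index)
    cols = list(samples) if samples is not None else list(expr.values.columns)
    idx = idx.loc[cols].to_numpy(dtype=float)
    values = expr.values[cols]

    rows = []
    n_absent = 0
    for label, hits in ((1, positive_hits), (0, negative_hits)):
        for g in hits:
            if g not in values.index:
                n_absent += 1
                continue
            rho, p = spearman(values.loc[g].to_numpy(), idx)
            rows.append((g, rho, p, label))
    per_gene = pd.DataFrame(rows, columns=["gene", "rho", "p", "label"]).set_index("gene")
    if per_gene["label"].sum() < 5 or (1 - per_gene["label"]).sum() < 5:
        raise ValueError(
            f"need >= 5 hit genes per class in the matrix; got "
            f"{int(per_gene['label'].sum())} positive / "
            f"{int((1 - per_gene['label']).sum())} negative"
        )
    per_gene["included"] = (per_gene["p"] < sig_alpha) if filter_significant else True
    kept = per_gene[per_gene["included"]]
    n_pos = int(kept["label"].sum())
    n_neg = len(kept) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"one class empty after the significance filter "
            f"({n_pos} positive, {n_neg} negative kept)"
        )
    fpr, tpr, thr, auc = roc_curve(kept["rho"].to_numpy(), kept["label"].to_numpy())
    return ConcordanceResult(per_gene, fpr, tpr, thr, auc, len(kept), n_absent)
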