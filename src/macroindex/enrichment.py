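"""Single-sample GSEA pathway scoring and preranked GSEA.

ssGSEA scores each sample independently: genes are ranked by expression
(descending, average ranks for ties) and the score is the sum over list
positions of the difference between the weighted in-set empirical CDF
(weights |rank value|^alpha) and the uniform out-of-set CDF. Scores are
min-max normalized by the global range across the whole score matrix, so
they are comparable between sets and samples.

Preranked GSEA walks a ranked gene list: hits increment the running sum
proportionally to |metric|^weight_p (normalized over the set), misses
decrement by 1/(N - |S|); the enrichment score is the maximum deviation.
Significance comes from gene-label permutations that preserve the set
size, with exact enumeration when the number of possible sets is small.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "PathwayScoreMatrix",
    "RankedList",
    "GseaResult",
    "ssgsea_score",
    "build_ranked_list",
    "preranked_gsea",
    "SsGSEAScorer",
]

PathwayScoreMatrix = pd.DataFrame  # set_names x sample_ids


@dataclass
class RankedList:
    """Genes with a real ranking metric, sorted descending (ties by gene id)."""

    genes: list[str]
    metric: np.ndarray
    metric_kind: str = "spearman_rho"

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("ranked list genes must be unique")
        order = sorted(range(len(self.genes)),
                       key=lambda i: (-self.metric[i], self.genes[i]))
        self.genes = [self.genes[i] for i in order]
        self.metric = np.asarray([self.metric[i] for i in order], dtype=float)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GseaResult:
    table: pd.DataFrame  # per set: es, nes, p, fdr, n_genes
    leading_edge: dict[str, list[str]]


def _ssgsea_sample(ranks: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Running-sum score for one sample given average ranks of all genes."""
    order = np.argsort(-ranks, kind="stable")  # descending expression
    r_sorted = ranks[order]
    hit_sorted = in_set[order]
    w = np.where(hit_sorted, np.abs(r_sorted) ** alpha, 0.0)
    w_total = w.sum()
    n_out = (~hit_sorted).sum()
    ecdf_in = np.cumsum(w) / w_total
    ecdf_out = np.cumsum(~hit_sorted) / n_out
    return float((ecdf_in - ecdf_out).sum())


def ssgsea_score(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> PathwayScoreMatrix:
    """ssGSEA score of every gene set in every sample.

    Sets with fewer than two genes present in the expression matrix are
    skipped with a warning. When ``normalize`` is set the whole score
    matrix is shifted and scaled by its global range.
    """
    values = expr.values
    gene_index = {g: i for i, g in enumerate(values.index)}
    ranks = stats.rankdata(values.to_numpy(), axis=0)  # average ranks, per sample
    rows, names = [], []
    for name in sets:
        present = [gene_index[g] for g in sets[name] if g in gene_index]
        n_missing = len(sets[name]) - len(present)
        if n_missing:
            warnings.warn(f"set {name!r}: {n_missing} gene(s) absent, dropped")
        if len(present) < 2:
            warnings.warn(f"set {name!r} has < 2 genes present; skipped")
            continue
        if len(present) == values.shape[0]:
            warnings.warn(f"set {name!r} covers every gene; skipped")
            continue
        in_set = np.zeros(values.shape[0], dtype=bool)
        in_set[present] = True
        rows.append([
            _ssgsea_sample(ranks[:, j], in_set, alpha) for j in range(values.shape[1])
        ])
        names.append(name)
    if not rows:
        raise ValueError("every gene set was skipped")
    scores = pd.DataFrame(rows, index=names, columns=values.columns)
    if normalize:
        lo, hi = scores.to_numpy().min(), scores.to_numpy().max()
        if hi > lo:
            scores = (scores - lo) / (hi - lo)
    return scores


def build_ranked_list(
    expr: ExpressionMatrix,
    target=None,
    groups: pd.Series | None = None,
    metric_kind: str = "spearman_rho",
) -> RankedList:
    """Rank all genes by Spearman rho with a target vector or by log2 FC.

    ``metric_kind="spearman_rho"`` requires ``target`` (a per-sample
    vector, e.g. the Macro index); ``"logFC"`` requires ``groups`` (a
    per-sample binary label whose two levels, sorted, are treated as
    low/high) and uses the difference of mean log2(TPM+1).
    """
    values = expr.values
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if metric_kind == "spearman_rho":
        t = pd.Series(target).loc[values.columns].to_numpy(dtype=float)
        if np.std(t) == 0:
            raise ValueError("target vector has zero variance")
        t_ranks = stats.rankdata(t)
        g_ranks = stats.rankdata(values.to_numpy(), axis=1)
        tz = (t_ranks - t_ranks.mean()) / t_ranks.std()
        gz_sd = g_ranks.std(axis=1)
        gz_sd[gz_sd == 0] = np.inf  # constant genes get rho 0
        metric = ((g_ranks - g_ranks.mean(axis=1, keepdims=True)) / gz_sd[:, None]) @ tz / len(t)
    elif metric_kind == "logFC":
        groups = pd.Series(groups).loc[values.columns]
        levels = sorted(groups.unique())
        if len(levels) != 2:
            raise ValueError("groups must have exactly two levels")
        log_expr = np.log2(values.to_numpy() + 1.0)
        hi = log_expr[:, (groups == levels[1]).to_numpy()].mean(axis=1)
        lo = log_expr[:, (groups == levels[0]).to_numpy()].mean(axis=1)
        metric = hi - lo
    else:
        raise ValueError(f"unknown metric_kind {metric_kind!r}")
    return RankedList(list(values.index), np.asarray(metric), metric_kind)


def _running_es(metric: np.ndarray, hit: np.ndarray, weight_p: float) -> tuple[float, int]:
    """Max-deviation enrichment score and its argmax position."""
    n = len(metric)
    n_hit = int(hit.sum())
    if n_hit == n:
        raise ValueError("gene set equals the entire list; miss decrement undefined")
    w = np.abs(metric) ** weight_p
    w_hit = np.where(hit, w, 0.0)
    total = w_hit.sum()
    if total == 0:  # all-zero metrics inside the set: fall back to uniform hits
        w_hit = hit.astype(float)
        total = w_hit.sum()
    steps = w_hit / total - (~hit) / (n - n_hit)
    running = np.cumsum(steps)
    pos = int(np.argmax(np.abs(running)))
    return float(running[pos]), pos


def preranked_gsea(
    rl: RankedList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
    exact_max_combinations: int = 100_000,
) -> GseaResult:
    """Preranked GSEA with gene-label permutation significance.

    The nominal p-value is one-sided on the sign of the observed ES. When
    the number of same-size gene subsets C(N, |S|) is at most
    ``exact_max_combinations`` the null is enumerated exhaustively and p
    is the exact tail fraction; otherwise ``n_perm`` seeded random draws
    are used with the (r + 1) / (n + 1) estimator. NES divides ES by the
    mean |permuted ES| of the same sign; FDR uses the pooled NES ratio
    method.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    metric = rl.metric
    genes = rl.genes
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    records = []
    leading = {}
    null_nes_pos, null_nes_neg = [], []
    obs_nes = {}
    for name in sets:
        members = [gene_pos[g] for g in sets[name] if g in gene_pos]
        size = len(members)
        if not (min_size <= size <= max_size) or size >= n:
            continue
        hit = np.zeros(n, dtype=bool)
        hit[members] = True
        es, pos = _running_es(metric, hit, weight_p)
        if es >= 0:
            lead_idx = [i for i in range(pos + 1) if hit[i]]
        else:
            lead_idx = [i for i in range(pos, n) if hit[i]]
        leading[name] = [genes[i] for i in lead_idx]

        exact = math.comb(n, size) <= exact_max_combinations
        if exact:
            perm_es = np.array([
                _running_es(metric, _mask(n, c), weight_p)[0]
                for c in combinations(range(n), size)
            ])
        else:
            perm_es = np.empty(n_perm)
            for b in range(n_perm):
                mask = np.zeros(n, dtype=bool)
                mask[rng.choice(n, size=size, replace=False)] = True
                perm_es[b] = _running_es(metric, mask, weight_p)[0]
        same_sign = perm_es >= 0 if es >= 0 else perm_es <= 0
        tail = np.abs(perm_es[same_sign]) >= abs(es) - 1e-12
        if exact:
            p = float(tail.sum()) / len(perm_es)
        else:
            p = (tail.sum() + 1.0) / (len(perm_es) + 1.0)
        denom = np.abs(perm_es[same_sign]).mean() if same_sign.any() else np.nan
        nes = es / denom if denom and not np.isnan(denom) else np.nan
        obs_nes[name] = nes
        with np.errstate(invalid="ignore", divide="ignore"):
            perm_nes_pos = perm_es[perm_es >= 0]
            perm_nes_neg = perm_es[perm_es < 0]
            if perm_nes_pos.size:
                null_nes_pos.extend(perm_nes_pos / perm_nes_pos.mean())
            if perm_nes_neg.size:
                null_nes_neg.extend(perm_nes_neg / abs(perm_nes_neg).mean())
        records.append((name, es, nes, min(p, 1.0), size))

    if not records:
        raise ValueError("no gene set passed the size filters")
    table = pd.DataFrame(records, columns=["set", "es", "nes", "p", "n_genes"]).set_index("set")

    # FDR: fraction of pooled null NES at least as extreme, relative to the
    # fraction of observed NES at least as extreme (clipped to [0, 1])
    null_pos = np.asarray(null_nes_pos)
    null_neg = np.asarray(null_nes_neg)
    obs_vals = table["nes"].to_numpy()
    fdrs = []
    for nes in obs_vals:
        if np.isnan(nes):
            fdrs.append(np.nan)
            continue
        if nes >= 0:
            null_frac = (null_pos >= nes).mean() if null_pos.size else 1.0
            obs_frac = (obs_vals[obs_vals >= 0] >= nes).mean()
        else:
            null_frac = (null_neg <= nes).mean() if null_neg.size else 1.0
            obs_frac = (obs_vals[obs_vals < 0] <= nes).mean()
        fdrs.append(min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0)
    table["fdr"] = fdrs
    return GseaResult(table, leading)


def _mask(n: int, idx) -> np.ndarray:
    m = np.zeros(n, dtype=bool)
    m[list(idx)] = True
    return m


class SsGSEAScorer:
    """Transformer mapping an expression matrix to pathway-activity scores.

    ``transform`` accepts an :class:`ExpressionMatrix` (or a genes x
    samples DataFrame) and returns a set x sample score DataFrame.
    """

    def __init__(self, gene_sets: GeneSetCollection, alpha: float = 0.25,
                 normalize: bool = True):
        self.gene_sets = gene_sets
        self.alpha = alpha
        self.normalize = normalize

    def get_params(self, deep: bool = True) -> dict:
        return {"gene_sets": self.gene_sets, "alpha": self.alpha,
                "normalize": self.normalize}

    def set_params(self, **params) -> "SsGSEAScorer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "SsGSEAScorer":
        return self  # stateless

    def transform(self, X) -> pd.DataFrame:
        if not isinstance(X, ExpressionMatrix):
            X = ExpressionMatrix(pd.DataFrame(X))
        return ssgsea_score(X, self.gene_sets, self.alpha, self.normalize)

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
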