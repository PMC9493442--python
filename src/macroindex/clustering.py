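"""Consensus clustering of immune-fraction profiles and Macro group labels.

Samples are clustered by PAM (k-medoids, build + swap) under the
correlation distance d(i, j) = 1 - Pearson(x_i, x_j), with repeated
subsampling accumulated into a consensus matrix per candidate k. The
number of clusters is chosen by minimizing the proportion of ambiguous
clustering (PAC): the fraction of off-diagonal consensus entries strictly
between u1 and u2. Core samples are the top 75% of each cluster by
silhouette width on the consensus dissimilarity. The two clusters are
crossed with histology to form the Macro1 (GBM, high-M2), Macro2 (LGG,
high-M2) and Macro3 (LGG, low-M2) groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable

__all__ = [
    "ConsensusResult",
    "MacroGroups",
    "ConsensusClusterer",
    "filter_fraction_matrix",
    "pearson_distance",
    "pam",
    "consensus_cluster",
    "compute_pac",
    "select_k",
    "silhouette_widths",
    "select_core_samples",
    "assign_macro_groups",
]


@dataclass
class ConsensusResult:
    consensus: dict[int, pd.DataFrame]  # k -> samples x samples consensus matrix
    assignments: dict[int, pd.Series]  # k -> sample -> cluster id (0-based)
    pac_by_k: dict[int, float] = field(default_factory=dict)
    chosen_k: int | None = None
    silhouette: pd.Series | None = None
    core_flag: pd.Series | None = None


@dataclass
class MacroGroups:
    labels: pd.Series  # sample -> {"Macro1","Macro2","Macro3"}
    cluster1_id: int
    unassigned: list[str] = field(default_factory=list)  # GBM in cluster 2


def filter_fraction_matrix(
    fractions: pd.DataFrame,
    pvalues: pd.Series | None = None,
    p_threshold: float = 0.05,
    zero_presence: float = 0.5,
) -> pd.DataFrame:
    """Drop unreliable samples and near-absent cell types.

    Samples with a deconvolution p-value above ``p_threshold`` are removed
    (when p-values are given); then cell types whose fraction is zero in
    strictly more than ``zero_presence`` of the remaining samples are
    removed.
    """
    out = fractions
    if pvalues is not None:
        keep = pvalues.loc[out.columns] <= p_threshold
        out = out.loc[:, keep[keep].index]
    zero_frac = (out.to_numpy() == 0).mean(axis=1)
    keep_types = zero_frac <= zero_presence  # "over half" is strict >
    out = out.loc[out.index[keep_types]]
    if out.shape[0] == 0:
        raise ValueError("all cell types removed by the zero-presence filter")
    return out


def pearson_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between sample rows of X."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"sample at position {bad} has a constant profile")
    C = np.corrcoef(X)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def pam(D: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """PAM k-medoids on a precomputed distance matrix (greedy build + swap).

    Returns 0-based cluster labels ordered so that cluster ids follow the
    first occurrence of each medoid's cluster among the samples.
    """
    n = D.shape[0]
    if k >= n:
        return np.arange(n)
    # build phase: first medoid minimizes total distance, then greedy adds
    medoids = [int(np.argmin(D.sum(axis=1)))]
    d_near = D[:, medoids[0]].copy()
    for _ in range(1, k):
        gains = np.maximum(d_near[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        m = int(np.argmax(gains))
        medoids.append(m)
        d_near = np.minimum(d_near, D[:, m])
    medoids = np.array(medoids)
    # swap phase
    for _ in range(max_iter):
        dm = D[:, medoids]  # n x k
        order = np.argsort(dm, axis=1)
        near = order[:, 0]
        d1 = dm[np.arange(n), near]
        d2 = dm[np.arange(n), order[:, 1]]
        best_delta, best_swap = 0.0, None
        for mi in range(k):
            # cost change of replacing medoid mi with each candidate h
            is_mine = near == mi
            # points not assigned to mi: new dist = min(d1, D[:, h])
            # points assigned to mi: new dist = min(d2, D[:, h])
            floor = np.where(is_mine, d2, d1)
            delta = np.minimum(D, floor[:, None]).sum(axis=0) - d1.sum()
            delta[medoids] = np.inf
            h = int(np.argmin(delta))
            if delta[h] < best_delta - 1e-12:
                best_delta, best_swap = float(delta[h]), (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    labels_raw = np.argmin(D[:, medoids], axis=1)
    # relabel clusters by first occurrence for determinism
    remap, nxt = {}, 0
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(labels_raw):
        if lab not in remap:
            remap[lab] = nxt
            nxt += 1
        labels[i] = remap[lab]
    return labels


def consensus_cluster(
    X: pd.DataFrame,
    k_range=range(2, 7),
    n_resample: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Subsampled PAM consensus matrices and assignments for each k.

    ``X`` is samples x features. For each k the consensus matrix entry
    M(i, j) is the fraction of co-subsampled iterations in which samples i
    and j landed in the same PAM cluster; the final assignment at each k
    is PAM on the dissimilarity 1 - M.
    """
    X = pd.DataFrame(X)
    samples = list(X.index)
    n = len(samples)
    ks = list(k_range)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if n < 2 * max(ks):
        raise ValueError("need at least 2 * k_max samples")
    D_full = pearson_distance(X.to_numpy())
    n_sub = max(2 * max(ks), int(math.floor(subsample_frac * n)))
    rng = np.random.default_rng(seed)

    consensus, assignments = {}, {}
    for k in ks:
        co_cluster = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        k_rng = np.random.default_rng(rng.integers(0, 2**31))
        for _ in range(n_resample):
            idx = np.sort(k_rng.choice(n, size=n_sub, replace=False))
            labels = pam(D_full[np.ix_(idx, idx)], k)
            co_sample[np.ix_(idx, idx)] += 1.0
            for lab in range(k):
                members = idx[labels == lab]
                co_cluster[np.ix_(members, members)] += 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0
        consensus[k] = pd.DataFrame(M, index=samples, columns=samples)
        assignments[k] = pd.Series(pam(1.0 - M, k), index=samples)
    return ConsensusResult(consensus=consensus, assignments=assignments)


def compute_pac(M: pd.DataFrame | np.ndarray, u1: float = 0.1, u2: float = 0.9) -> float:
    """Proportion of ambiguous clustering: off-diagonal entries strictly in (u1, u2)."""
    if not 0 <= u1 < u2 <= 1:
        raise ValueError("need 0 <= u1 < u2 <= 1")
    A = np.asarray(M, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("consensus matrix must be symmetric")
    iu = np.triu_indices_from(A, k=1)
    vals = A[iu]
    return float(((vals > u1) & (vals < u2)).mean())


def select_k(pac_by_k: dict[int, float]) -> int:
    """k minimizing PAC; ties broken toward the smallest k."""
    return min(sorted(pac_by_k), key=lambda k: (pac_by_k[k], k))


def silhouette_widths(D: pd.DataFrame | np.ndarray, assignments: pd.Series) -> pd.Series:
    """Per-sample silhouette width s(i) = (b - a) / max(a, b) on distances D.

    ``a`` is the mean intra-cluster distance (excluding self); ``b`` the
    smallest mean distance to another cluster. Members of singleton
    clusters get s = 0.
    """
    assignments = pd.Series(assignments)
    labels = assignments.to_numpy()
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    A = np.asarray(D, dtype=float)
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        mask_own = (labels == own)
        n_own = mask_own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = A[i, mask_own].sum() / (n_own - 1)
        b = min(A[i, labels == other].mean() for other in uniq if other != own)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return pd.Series(s, index=assignments.index)


def select_core_samples(
    silhouette: pd.Series, assignments: pd.Series, keep_frac: float = 0.75
) -> pd.Series:
    """Flag the top ``keep_frac`` of each cluster by silhouette width.

    Keeps ceil(keep_frac * cluster size) samples per cluster; ties at the
    cutoff are broken by sample id order for determinism.
    """
    silhouette = pd.Series(silhouette)
    assignments = pd.Series(assignments)
    flags = pd.Series(False, index=assignments.index)
    for _, members in assignments.groupby(assignments):
        ids = list(members.index)
        n_keep = math.ceil(keep_frac * len(ids))
        ranked = sorted(ids, key=lambda s: (-silhouette[s], s))
        flags[ranked[:n_keep]] = True
    return flags


def assign_macro_groups(
    assignments: pd.Series,
    core_flag: pd.Series,
    clin: ClinicalTable,
    m2: pd.Series,
    gbm_label: str = "Glioblastoma",
) -> MacroGroups:
    """Cross the two clusters with histology into Macro1/2/3 labels.

    The cluster with the higher mean M2 fraction is cluster 1. Core GBM
    samples in cluster 1 become Macro1, core LGG samples in cluster 1
    Macro2, and core LGG samples in cluster 2 Macro3; GBM samples in
    cluster 2 are reported as unassigned.
    """
    assignments = pd.Series(assignments)
    clusters = np.unique(assignments)
    if len(clusters) != 2:
        raise ValueError(f"macro groups require exactly 2 clusters, got {len(clusters)}")
    hist = clin.require("histology")["histology"]
    means = {c: m2[assignments[assignments == c].index].mean() for c in clusters}
    if math.isclose(means[clusters[0]], means[clusters[1]], rel_tol=0, abs_tol=1e-12):
        raise ValueError("clusters have identical mean M2 fraction; orientation undecidable")
    cluster1 = max(means, key=means.get)
    labels = {}
    unassigned = []
    for s in assignments.index:
        if not core_flag[s]:
            continue
        is_gbm = hist[s] == gbm_label
        in_c1 = assignments[s] == cluster1
        if in_c1 and is_gbm:
            labels[s] = "Macro1"
        elif in_c1:
            labels[s] = "Macro2"
        elif not is_gbm:
            labels[s] = "Macro3"
        else:
            unassigned.append(s)
    return MacroGroups(pd.Series(labels, name="macro_group"), int(cluster1), unassigned)


class ConsensusClusterer:
    """Consensus PAM clustering estimator over immune-fraction profiles.

    scikit-learn-style interface: ``fit(X)`` consumes a samples x features
    DataFrame (or array) and exposes ``labels_``, ``consensus_``,
    ``pac_by_k_``, ``chosen_k_``, ``silhouette_`` and ``core_flag_``.

    Parameters
    ----------
    k_min, k_max : candidate cluster numbers (inclusive).
    n_resample : subsampling iterations per k.
    subsample_frac : fraction of samples drawn per iteration.
    pac_lower, pac_upper : PAC ambiguity window (u1, u2).
    keep_frac : fraction of each cluster kept as core samples.
    random_state : seed of the single generator driving subsampling.
    """

    def __init__(
        self,
        k_min: int = 2,
        k_max: int = 6,
        n_resample: int = 1000,
        subsample_frac: float = 0.8,
        pac_lower: float = 0.1,
        pac_upper: float = 0.9,
        keep_frac: float = 0.75,
        random_state: int = 0,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.n_resample = n_resample
        self.subsample_frac = subsample_frac
        self.pac_lower = pac_lower
        self.pac_upper = pac_upper
        self.keep_frac = keep_frac
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "k_min", "k_max", "n_resample", "subsample_frac",
                "pac_lower", "pac_upper", "keep_frac", "random_state",
            )
        }

    def set_params(self, **params) -> "ConsensusClusterer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "ConsensusClusterer":
        X = pd.DataFrame(X)
        res = consensus_cluster(
            X,
            k_range=range(self.k_min, self.k_max + 1),
            n_resample=self.n_resample,
            subsample_frac=self.subsample_frac,
            seed=self.random_state,
        )
        res.pac_by_k = {
            k: compute_pac(M, self.pac_lower, self.pac_upper)
            for k, M in res.consensus.items()
        }
        res.chosen_k = select_k(res.pac_by_k)
        M = res.consensus[res.chosen_k]
        assign = res.assignments[res.chosen_k]
        res.silhouette = silhouette_widths(1.0 - M.to_numpy(), assign)
        res.core_flag = select_core_samples(res.silhouette, assign, self.keep_frac)
        self.result_ = res
        self.labels_ = assign.to_numpy()
        self.consensus_ = M
        self.pac_by_k_ = res.pac_by_k
        self.chosen_k_ = res.chosen_k
        self.silhouette_ = res.silhouette
        self.core_flag_ = res.core_flag
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
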