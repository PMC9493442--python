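"""Regression-consensus framework linking features to the M2 fraction,
plus the shared statistics kernel.

The central idea: each feature (pathway score, gene, alteration) is
regressed against the M2 macrophage fraction estimated by several
independent deconvolution algorithms. A feature is called associated
("consensus verdict") only when two or more algorithms yield a significant
coefficient of the same sign and no algorithm is significant with the
opposite sign. The consensus rule is the error control; no additional
multiple-testing correction is applied at this step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "ContingencyTable",
    "ConsensusRegressionReport",
    "vif_reduce",
    "fit_m2_regression",
    "consensus_significance",
    "fit_alteration_logistic",
    "fisher_exact_rxc",
    "wilcoxon_rank_sum",
    "spearman",
]


# ---------------------------------------------------------------------------
# contingency tables and the Freeman-Halton exact test
# ---------------------------------------------------------------------------


@dataclass
class ContingencyTable:
    """r x c table of nonnegative integer counts with labels."""

    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValueError("contingency table must be 2-dimensional")
        if (arr < 0).any() or not np.issubdtype(np.asarray(arr).dtype, np.integer) and not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be nonnegative integers")
        self.counts = np.round(arr).astype(np.int64)
        if self.counts.sum() <= 0:
            raise ValueError("contingency table total must be > 0")
        if not self.row_labels:
            self.row_labels = [f"r{i}" for i in range(arr.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"c{j}" for j in range(arr.shape[1])]


def _enumerate_tables(row_margins, col_margins, log_obs, log_margin_const, tol):
    """Depth-first enumeration of all tables with the given margins.

    Accumulates the probability of tables whose probability is <= the
    observed table's probability (with relative tolerance ``tol``).
    Returns (p_sum, n_tables_visited).
    """
    r, c = len(row_margins), len(col_margins)
    lg = math.lgamma
    p_sum = 0.0
    visited = 0
    cell_logfact_threshold = log_margin_const - log_obs  # sum log n_ij! >= this

    col_rem = list(col_margins)
    table_logfact = [0.0]

    def recurse(i, j, row_rem):
        nonlocal p_sum, visited
        if i == r - 1:
            # last row fully determined by the column remainders
            s = table_logfact[0] + sum(lg(x + 1) for x in col_rem)
            visited += 1
            if s >= cell_logfact_threshold - abs(cell_logfact_threshold) * tol - 1e-12:
                p_sum += math.exp(log_margin_const - s)
            return
        if j == c - 1:
            x = row_rem
            if x > col_rem[j]:
                return
            col_rem[j] -= x
            table_logfact[0] += lg(x + 1)
            recurse(i + 1, 0, row_margins[i + 1])
            table_logfact[0] -= lg(x + 1)
            col_rem[j] += x
            return
        lo = max(0, row_rem - sum(col_rem[j + 1:]))
        hi = min(row_rem, col_rem[j])
        for x in range(lo, hi + 1):
            col_rem[j] -= x
            table_logfact[0] += lg(x + 1)
            recurse(i, j + 1, row_rem - x)
            table_logfact[0] -= lg(x + 1)
            col_rem[j] += x

    recurse(0, 0, row_margins[0])
    return p_sum, visited


def _count_tables_upper_bound(row_margins, col_margins) -> float:
    # loose product bound on the number of tables with the given margins
    bound = 1.0
    for i, ri in enumerate(row_margins[:-1]):
        for j, cj in enumerate(col_margins[:-1]):
            bound *= min(ri, cj) + 1
    return bound


def fisher_exact_rxc(
    table: ContingencyTable | np.ndarray,
    max_tables: float = 1e7,
    n_mc: int = 1_000_000,
    seed: int = 0,
    rel_tol: float = 1e-7,
) -> dict:
    """Two-sided Fisher exact test for an r x c table (Freeman-Halton).

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of tables no more probable than the
    observed one. When the enumeration workload exceeds ``max_tables``, a
    seeded Monte-Carlo estimate over ``n_mc`` tables drawn from the null
    (via ``scipy.stats.random_table``) is returned with its standard error.

    Returns a dict with keys ``p``, ``method`` ("exact" or "monte-carlo"),
    and ``se`` (None for exact).
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    counts = table.counts
    r, c = counts.shape
    if r < 2 or c < 2:
        raise ValueError("need at least a 2x2 table")
    row_margins = counts.sum(axis=1)
    col_margins = counts.sum(axis=0)
    if (row_margins == 0).any() or (col_margins == 0).any():
        raise ValueError("zero row or column margin")
    n = counts.sum()
    lg = math.lgamma
    log_margin_const = (
        sum(lg(x + 1) for x in row_margins)
        + sum(lg(x + 1) for x in col_margins)
        - lg(n + 1)
    )
    log_obs = log_margin_const - sum(lg(x + 1) for x in counts.ravel())

    if _count_tables_upper_bound(list(row_margins), list(col_margins)) <= max_tables:
        p, _ = _enumerate_tables(
            list(int(x) for x in row_margins),
            list(int(x) for x in col_margins),
            log_obs,
            log_margin_const,
            rel_tol,
        )
        return {"p": min(p, 1.0), "method": "exact", "se": None}

    rng = np.random.default_rng(seed)
    dist = stats.random_table(row_margins, col_margins)
    draws = dist.rvs(n_mc, method="patefield", random_state=rng)
    logp = dist.logpmf(draws)
    hits = (logp <= log_obs + abs(log_obs) * rel_tol + 1e-12).mean()
    se = math.sqrt(hits * (1 - hits) / n_mc)
    return {"p": float(hits), "method": "monte-carlo", "se": se}


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x, y, exact_below_n: int = 25) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact null enumeration when both samples have size <= the
    threshold and there are no ties; otherwise a normal approximation with
    tie and continuity corrections.

    Returns (p, U statistic).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(x) <= exact_below_n) and (len(y) <= exact_below_n) and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue), float(res.statistic)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho, _ = stats.spearmanr(x, y)
    n = len(x)
    if n < 3 or not np.isfinite(rho):
        return float(rho), float("nan")
    if abs(rho) >= 1.0:
        return float(rho), 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# collinearity reduction and regression
# ---------------------------------------------------------------------------


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF_j = 1 / (1 - R^2) from regressing predictor j on the others."""
    others = np.delete(X, j, axis=1)
    others = np.column_stack([np.ones(len(X)), others])
    y = X[:, j]
    beta, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
    resid = y - others @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 0:
        return float("inf")
    r2 = 1 - ss_res / ss_tot
    if r2 >= 1 - 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2)


def vif_reduce(X: pd.DataFrame, threshold: float = 5.0) -> list[str]:
    """Backward-eliminate predictors until every VIF is below ``threshold``.

    At each step the predictor with the largest VIF is dropped; ties (and
    perfectly collinear pairs, whose VIF is infinite) are broken by
    dropping the later predictor in name order.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        return list(X.columns)
    kept = list(X.columns)
    while len(kept) >= 2:
        arr = X[kept].to_numpy(dtype=float)
        vifs = np.array([_vif_one(arr, j) for j in range(len(kept))])
        worst = np.max(vifs)
        if worst < threshold:
            break
        # candidates tied for the worst VIF (inf >= inf holds); drop the later by name
        tied = [kept[j] for j in range(len(kept)) if vifs[j] >= worst]
        drop = sorted(tied)[-1]
        kept.remove(drop)
    return kept


def fit_m2_regression(
    m2: pd.Series, X: pd.DataFrame, algorithm_tag: str = ""
) -> pd.DataFrame:
    """OLS of the M2 fraction on all predictors jointly, plus intercept.

    Returns a DataFrame indexed by predictor with columns ``beta``, ``p``
    and ``algorithm``. ``X`` is expected to have been vif-reduced first.
    """
    m2 = pd.Series(m2).astype(float)
    X = pd.DataFrame(X).astype(float)
    if len(m2) <= X.shape[1] + 1:
        raise ValueError("need n > p + 1 samples for OLS")
    design = sm.add_constant(X, has_constant="add")
    model = sm.OLS(m2.to_numpy(), design.to_numpy())
    try:
        fit = model.fit()
    except np.linalg.LinAlgError as e:  # pragma: no cover - precluded by vif_reduce
        raise ValueError(f"singular design matrix: {e}") from e
    out = pd.DataFrame(
        {
            "beta": fit.params[1:],
            "p": fit.pvalues[1:],
            "algorithm": algorithm_tag,
        },
        index=X.columns,
    )
    return out


@dataclass
class ConsensusRegressionReport:
    """Per-feature x per-algorithm coefficients plus the consensus verdict."""

    per_algorithm: pd.DataFrame  # long format: feature, algorithm, beta, p
    verdicts: pd.Series  # feature -> {"positive", "negative", "none"}


def consensus_significance(
    reports: list[pd.DataFrame], alpha: float = 0.05
) -> ConsensusRegressionReport:
    """Sign-consensus verdict across per-algorithm regression reports.

    A feature is ``positive`` when >= 2 algorithms are significant
    (p < alpha) with beta > 0 and no algorithm is significant with
    beta < 0; mirrored for ``negative``; otherwise ``none``.
    """
    if len(reports) < 2:
        raise ValueError("need reports from at least two algorithms")
    long = pd.concat(
        [df.reset_index(names="feature") for df in reports], ignore_index=True
    )
    verdicts = {}
    for feature, grp in long.groupby("feature", sort=False):
        sig = grp[grp["p"] < alpha]
        n_pos = int((sig["beta"] > 0).sum())
        n_neg = int((sig["beta"] < 0).sum())
        if n_pos >= 2 and n_neg == 0:
            verdicts[feature] = "positive"
        elif n_neg >= 2 and n_pos == 0:
            verdicts[feature] = "negative"
        else:
            verdicts[feature] = "none"
    return ConsensusRegressionReport(long, pd.Series(verdicts, name="verdict"))


def fit_alteration_logistic(
    alterations: pd.DataFrame, m2: pd.Series, algorithm_tag: str = ""
) -> pd.DataFrame:
    """Logistic regression of each binary alteration on the M2 fraction.

    The alteration indicator is the response and the standardized M2
    fraction the sole predictor; the Wald p-value is reported. Features
    with complete separation (or too few samples in either class) are
    flagged with ``estimable = False`` and NaN beta/p.
    """
    m2 = pd.Series(m2).astype(float)
    z = (m2 - m2.mean()) / m2.std(ddof=0)
    design = sm.add_constant(z.to_numpy())
    rows = []
    for feature in alterations.index:
        y = alterations.loc[feature].to_numpy(dtype=float)
        n1 = int(y.sum())
        n0 = len(y) - n1
        if n1 < 3 or n0 < 3:
            rows.append((feature, np.nan, np.nan, False, "class with < 3 samples"))
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", True) or abs(fit.params[1]) > 50:
                rows.append((feature, np.nan, np.nan, False, "non-convergence"))
                continue
            rows.append((feature, float(fit.params[1]), float(fit.pvalues[1]), True, ""))
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            rows.append((feature, np.nan, np.nan, False, "complete separation"))
    out = pd.DataFrame(
        rows, columns=["feature", "beta", "p", "estimable", "flag"]
    ).set_index("feature")
    out["algorithm"] = algorithm_tag
    return out
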