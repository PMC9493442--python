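"""Survival analysis of index-derived groups: Kaplan-Meier, log-rank,
univariate Cox proportional hazards, and relapse-interval grouping.

lifelines supplies the estimators (KM with Greenwood variance, log-rank,
Cox partial likelihood with Efron tie handling); this module adapts them
to the pipeline's tables and adds the early/late relapse rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .io import ClinicalTable

__all__ = [
    "SurvivalFit",
    "CoxResult",
    "km_fit",
    "logrank_test",
    "cox_univariate",
    "relapse_groups",
    "DAYS_PER_MONTH",
    "DAYS_PER_YEAR",
]

DAYS_PER_MONTH = 30.44
DAYS_PER_YEAR = 365.25


@dataclass
class SurvivalFit:
    """Product-limit estimates per group on that group's event-time grid."""

    groups: dict[str, pd.DataFrame]  # group -> timeline, survival, ci, n at risk


@dataclass
class CoxResult:
    coef: float
    se: float
    z: float
    p: float
    hr: float
    hr_ci: tuple[float, float]
    converged: bool
    flag: str = ""


def _validate(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be binary 0/1")
    return times, events.astype(int)


def km_fit(times, events, groups) -> SurvivalFit:
    """Kaplan-Meier curves per group with Greenwood confidence intervals."""
    times, events = _validate(times, events)
    groups = pd.Series(list(groups))
    out = {}
    for level in groups.unique():
        mask = (groups == level).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(level))
        table = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_[str(level)].to_numpy(),
            "ci_lower": kmf.confidence_interval_.iloc[:, 0].to_numpy(),
            "ci_upper": kmf.confidence_interval_.iloc[:, 1].to_numpy(),
            "n_at_risk": [
                int((times[mask] >= t).sum()) for t in kmf.survival_function_.index
            ],
        })
        out[str(level)] = table
    return SurvivalFit(out)


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p)."""
    times, events = _validate(times, events)
    groups = pd.Series(list(groups))
    levels = groups.unique()
    if len(levels) != 2:
        raise ValueError("log-rank here compares exactly two groups")
    m = (groups == levels[0]).to_numpy()
    res = _ll_logrank(times[m], times[~m], events[m], events[~m])
    return float(res.test_statistic), float(res.p_value)


def cox_univariate(times, events, covariate) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron ties).

    Requires at least 10 events. Non-convergence or a monotone likelihood
    (e.g. a perfectly separating covariate) yields a flagged result with
    NaN estimates rather than an exception.
    """
    times, events = _validate(times, events)
    covariate = np.asarray(covariate, dtype=float)
    if events.sum() < 10:
        raise ValueError(f"need >= 10 events, got {int(events.sum())}")
    if np.std(covariate) == 0:
        raise ValueError("covariate is constant; no information")
    df = pd.DataFrame({"time": times, "event": events, "x": covariate})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as e:
        return CoxResult(np.nan, np.nan, np.nan, np.nan, np.nan,
                         (np.nan, np.nan), False, f"non-convergence: {e}")
    s = cph.summary.loc["x"]
    return CoxResult(
        coef=float(s["coef"]),
        se=float(s["se(coef)"]),
        z=float(s["z"]),
        p=float(s["p"]),
        hr=float(np.exp(s["coef"])),
        hr_ci=(float(np.exp(s["coef lower 95%"])), float(np.exp(s["coef upper 95%"]))),
        converged=True,
    )


def relapse_groups(clin: ClinicalTable, cohort_kind: str) -> pd.Series:
    """Early/late relapse labels from the progression-free interval.

    GBM: early = PFI < 6 months with a progression event; late = PFI > 12
    months. LGG: the cutoff is 5 years on both sides. "Early" requires an
    observed event; "late" admits censoring beyond the cutoff. Samples in
    the gap (or censored before the late cutoff) are excluded.
    """
    if cohort_kind not in ("GBM", "LGG"):
        raise ValueError("cohort_kind must be 'GBM' or 'LGG'")
    df = clin.require("pfi_time", "pfi_event")
    if cohort_kind == "GBM":
        early_cut = 6 * DAYS_PER_MONTH
        late_cut = 12 * DAYS_PER_MONTH
    else:
        early_cut = late_cut = 5 * DAYS_PER_YEAR
    t = df["pfi_time"].astype(float)
    e = df["pfi_event"].astype(int)
    labels = pd.Series(index=df.index, dtype=object)
    labels[(t < early_cut) & (e == 1)] = "early"
    labels[t > late_cut] = "late"
    return labels.dropna()
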